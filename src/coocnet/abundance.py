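"""Relative abundance, rare/abundant classification, top-N selection and
ternary coordinates.

"Relative abundance" of an OTU is the arithmetic mean of its per-sample
proportions over the samples in scope (one group, or all groups pooled),
i.e. abundance averaged over samples rather than pooled counts.  OTUs are
partitioned into three classes by mean relative abundance:

* rare      — mean < 0.01 %
* abundant  — mean > 0.1 %
* moderate  — 0.01 % <= mean <= 0.1 % (both bounds inclusive)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

RARE_THRESHOLD = 1e-4  # 0.01 % as a proportion
ABUNDANT_THRESHOLD = 1e-3  # 0.1 % as a proportion

CLASSES = ("rare", "moderate", "abundant")


@dataclass
class AbundanceProfile:
    """Per-OTU mean relative abundances and abundance classes.

    Attributes
    ----------
    overall_mean
        Mean per-sample proportion of each OTU over all samples in scope.
    group_mean
        OTU x group matrix of group-wise mean proportions.
    abundance_class
        One of ``rare | moderate | abundant`` per OTU.
    """

    overall_mean: pd.Series
    group_mean: pd.DataFrame
    abundance_class: pd.Series


def classify(mean_abundance: float) -> str:
    """Classify one mean relative abundance (a proportion in [0, 1])."""
    if mean_abundance < RARE_THRESHOLD:
        return "rare"
    if mean_abundance > ABUNDANT_THRESHOLD:
        return "abundant"
    return "moderate"


def sample_proportions(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances (each row sums to 1)."""
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return table.counts.div(totals, axis=0)


def relative_abundance(table: OtuTable) -> AbundanceProfile:
    """Compute the abundance profile of a table.

    The classification uses the mean over exactly the samples present in
    ``table`` — pass a single group's table to classify within a group,
    or the full table to classify over all samples pooled.
    """
    props = sample_proportions(table)
    overall = props.mean(axis=0)
    group_mean = props.groupby(table.groups).mean().T
    klass = overall.map(classify)
    klass.name = "abundance_class"
    overall.name = "overall_mean"
    return AbundanceProfile(
        overall_mean=overall, group_mean=group_mean, abundance_class=klass
    )


def select_top_otus(profile: AbundanceProfile, n: int) -> list[str]:
    """The ``n`` OTU ids with the highest mean relative abundance.

    Sorted by mean descending; ties broken by OTU id ascending so the
    selection is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        profile.overall_mean.index, key=lambda o: (-profile.overall_mean[o], o)
    )
    return ranked[: min(n, len(ranked))]


def ternary_coordinates(
    table: OtuTable, otus: list[str] | None = None
) -> pd.DataFrame:
    """Per-OTU group-mean abundances normalised to sum to 1.

    Requires exactly three groups; the resulting triple places each OTU
    in the three-population simplex (a ternary plot).  An OTU absent
    from every group sits at the centroid (1/3, 1/3, 1/3).
    """
    groups = table.group_names
    if len(groups) != 3:
        raise ValueError(
            f"ternary coordinates need exactly 3 groups, got {len(groups)}"
        )
    profile = relative_abundance(table)
    gm = profile.group_mean[groups]
    if otus is not None:
        gm = gm.loc[list(otus)]
    totals = gm.sum(axis=1)
    coords = gm.div(totals.where(totals > 0, np.nan), axis=0)
    coords = coords.fillna(1.0 / 3.0)
    return coords
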