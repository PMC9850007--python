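"""Synthetic grouped OTU count tables with planted modular correlation
structure.

The generator emulates the statistical shape of a multi-population 16S
survey: several sample groups, thousands of OTUs with a heavy-tailed
(log-normal) abundance spectrum spanning rare (< 0.01 %), moderate and
abundant (> 0.1 %) classes, and planted blocks of co-varying OTUs that
induce modular Spearman correlation structure with designated hub and
connector nodes.

Mechanism, per sample:

1. per-OTU baseline abundances are drawn once from a log-normal
   (``abundance_lognormal_mu``, ``abundance_lognormal_sigma``);
2. each planted module has one latent N(0, 1) factor per sample; every
   member OTU adds that factor to its log-abundance, scaled by a
   loading derived from ``intra_module_correlation``.  Planted hubs get
   the largest loading in their module; planted connectors load equally
   on two modules (their own and the next), so their module identity is
   deliberately ambiguous — recovery metrics should score the
   unambiguous planted members;
3. independent Gaussian noise with sd ``noise_sd`` is added on the log
   scale;
4. the sample's abundances are converted to counts by one multinomial
   draw at ``sequencing_depth`` (row sums are exact).

Module membership is planted on the highest-baseline OTUs so that the
planted correlation signal is observable after multinomial sampling;
everything else is uncorrelated background.  Regular members get
heterogeneous loadings (uniform on [0.3, 0.9] of the full loading) so
that within-module degree varies and hubs genuinely dominate their
module, as in real co-occurrence networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RANKS, OtuTable

_HUB_LOADING = 1.4
_CONNECTOR_HOME_LOADING = 1.2
_CONNECTOR_AWAY_LOADING = 1.2
_MEMBER_LOADING_RANGE = (0.33, 0.55)
#: Planted OTUs are placed below the extreme top of the abundance
#: spectrum so that their combined share of the community stays modest:
#: latent factors acting on taxa that dominate the composition would
#: otherwise move every other taxon's relative abundance through the
#: shared denominator and induce spurious background correlations.  The
#: cap shrinks as the factor loading grows, because the denominator
#: swing scales with the loading.
_PLANTED_SHARE_MAX = 0.05
_REFERENCE_LOADING = 1.5


def _planted_share_cap(lam: float) -> float:
    if lam <= _REFERENCE_LOADING:
        return _PLANTED_SHARE_MAX
    return _PLANTED_SHARE_MAX * (_REFERENCE_LOADING / lam) ** 4

_PHYLA = (
    "Proteobacteria", "Firmicutes", "Bacteroidetes",
    "Actinobacteria", "Verrucomicrobia", "Planctomycetes",
)
_FAMILIES = (
    "Pseudomonadaceae", "Clostridiaceae", "Enterobacteriaceae",
    "Lactobacillaceae", "Flavobacteriaceae", "Streptococcaceae",
    "Comamonadaceae", "Oxalobacteraceae", "Sphingomonadaceae",
)
_GENERA = (
    "Pseudomonas", "Clostridium", "Escherichia-Shigella", "Lactobacillus",
    "Flavobacterium", "Streptococcus", "Herbaspirillum", "Bacteriovorax",
    "Pedobacter", "Serratia",
)


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic OTU-table generator.

    Defaults describe a three-population survey of 207/139/148 samples,
    3000 OTUs at 50,000 reads per sample, with four planted modules of
    20 OTUs whose members share a latent factor strong enough to give a
    within-module rank correlation around
    ``intra_module_correlation``.
    """

    n_groups: int = 3
    samples_per_group: tuple[int, ...] = (207, 139, 148)
    n_otus: int = 3000
    n_modules: int = 4
    module_size: int = 20
    intra_module_correlation: float = 0.9
    hub_fraction: float = 0.05
    connector_fraction: float = 0.1
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 2.0
    sequencing_depth: int = 50_000
    noise_sd: float = 0.5
    seed: int = 0
    group_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be positive")
        if self.abundance_lognormal_sigma <= 0:
            raise ConfigError("abundance_lognormal_sigma must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("intra_module_correlation", "hub_fraction", "connector_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if len(self.samples_per_group) != self.n_groups:
            raise ConfigError(
                "samples_per_group must have one entry per group"
            )
        if self.n_modules * self.module_size > self.n_otus:
            raise ConfigError("planted modules exceed n_otus")
        if self.group_names is not None and len(self.group_names) != self.n_groups:
            raise ConfigError("group_names must have one entry per group")

    @property
    def resolved_group_names(self) -> tuple[str, ...]:
        if self.group_names is not None:
            return tuple(self.group_names)
        return tuple(f"group{i + 1}" for i in range(self.n_groups))


@dataclass
class GroundTruth:
    """Planted structure of a simulated table: module membership plus
    the designated hub and connector OTUs."""

    otu_module: dict[str, object]  # module id (int) or "background"
    planted_hubs: set[str] = field(default_factory=set)
    planted_connectors: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.planted_hubs & self.planted_connectors:
            raise ValueError("hubs and connectors must be disjoint")

    @property
    def planted_otus(self) -> list[str]:
        return sorted(
            o for o, m in self.otu_module.items() if m != "background"
        )

    @property
    def unambiguous_otus(self) -> list[str]:
        """Planted OTUs excluding connectors.

        ``otu_module`` records a connector under its nominal module, but
        a connector loads equally on two modules, so only non-connector
        members carry an unambiguous module label for recovery scoring.
        """
        return [o for o in self.planted_otus if o not in self.planted_connectors]


def _loading_scale(rho: float, noise_sd: float) -> float:
    """Factor loading giving latent (log-scale) correlation ``rho``
    between two full-loading members in the presence of ``noise_sd``."""
    if rho <= 0:
        return 0.0
    r = min(rho, 0.99)
    if noise_sd == 0:
        return 1.0  # any positive loading gives correlation 1 without noise
    return noise_sd * np.sqrt(r / (1.0 - r))


def _synthetic_taxonomy(
    rng: np.random.Generator, otu_ids: list[str], module_of: dict[str, object]
) -> pd.DataFrame:
    """7-rank lineages from a small fixed vocabulary; members of one
    module are biased toward one phylum so composition summaries have
    structure to find."""
    rows = []
    for otu in otu_ids:
        m = module_of.get(otu, "background")
        if m != "background" and rng.random() < 0.8:
            phylum = _PHYLA[(int(m) - 1) % len(_PHYLA)]
        else:
            phylum = _PHYLA[rng.integers(len(_PHYLA))]
        family = _FAMILIES[rng.integers(len(_FAMILIES))]
        genus = _GENERA[rng.integers(len(_GENERA))]
        lineage = [
            "Bacteria",
            phylum,
            "unknown",
            "unknown",
            family if rng.random() < 0.9 else "unknown",
            genus if rng.random() < 0.8 else "unknown",
            "unknown",
        ]
        rows.append(lineage)
    return pd.DataFrame(rows, index=otu_ids, columns=list(RANKS))


def simulate_otu_table(config: SimulationConfig) -> tuple[OtuTable, GroundTruth]:
    """Generate one grouped OTU count table plus its ground truth.

    All randomness flows from a single generator seeded with
    ``config.seed``; the same configuration always yields an identical
    table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = int(sum(config.samples_per_group))
    width = max(4, len(str(config.n_otus)))
    otu_ids = [f"OTU_{i + 1:0{width}d}" for i in range(config.n_otus)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    group_labels = []
    for name, size in zip(config.resolved_group_names, config.samples_per_group):
        group_labels.extend([name] * size)

    baselines = rng.lognormal(
        config.abundance_lognormal_mu,
        config.abundance_lognormal_sigma,
        config.n_otus,
    )

    # Plant modules on high—but not top—baseline OTUs: high enough that
    # the signal survives multinomial sampling, low enough that the
    # planted mass share stays below _PLANTED_SHARE_MAX (see above).
    n_planted = config.n_modules * config.module_size
    lam = _loading_scale(config.intra_module_correlation, config.noise_sd)
    share_cap = _planted_share_cap(lam)
    by_baseline = np.argsort(-baselines, kind="stable")
    total_mass = baselines.sum()
    skip = 0
    while skip + n_planted < config.n_otus:
        share = baselines[by_baseline[skip : skip + n_planted]].sum() / total_mass
        if share <= share_cap:
            break
        skip += max(1, n_planted // 10)
    planted_idx = by_baseline[skip : skip + n_planted]
    module_of: dict[str, object] = {o: "background" for o in otu_ids}
    member_idx: dict[int, list[int]] = {m + 1: [] for m in range(config.n_modules)}
    # deal round-robin so every module spans the same abundance range
    # (the first, largest-baseline member of each module becomes its hub)
    for pos, i in enumerate(planted_idx):
        m = pos % config.n_modules + 1
        member_idx[m].append(i)
        module_of[otu_ids[i]] = m

    n_hubs = max(1, round(config.hub_fraction * config.module_size)) if n_planted else 0
    n_conn = max(1, round(config.connector_fraction * config.module_size)) if n_planted else 0

    # loadings[i, m] = weight of module-m factor in OTU i's log-abundance
    loadings = np.zeros((config.n_otus, config.n_modules))
    hubs: set[str] = set()
    connectors: set[str] = set()
    for m in range(1, config.n_modules + 1):
        members = member_idx[m]
        u = rng.uniform(*_MEMBER_LOADING_RANGE, size=len(members))
        for pos, i in enumerate(members):
            loadings[i, m - 1] = u[pos] * lam
        for i in members[:n_hubs]:
            loadings[i, m - 1] = _HUB_LOADING * lam
            hubs.add(otu_ids[i])
        partner = m % config.n_modules + 1
        if partner != m:
            # connectors load on their nominal module and its cyclic
            # partner with equal weight, genuinely bridging the two
            for i in members[n_hubs : n_hubs + n_conn]:
                loadings[i, m - 1] = _CONNECTOR_HOME_LOADING * lam
                loadings[i, partner - 1] = _CONNECTOR_AWAY_LOADING * lam
                connectors.add(otu_ids[i])

    factors = rng.standard_normal((n_samples, config.n_modules))
    log_abund = np.log(baselines)[None, :] + factors @ loadings.T
    if config.noise_sd > 0:
        log_abund = log_abund + rng.normal(
            0.0, config.noise_sd, size=(n_samples, config.n_otus)
        )

    abund = np.exp(log_abund)
    probs = abund / abund.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, config.n_otus), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(config.sequencing_depth, probs[s])

    taxonomy = _synthetic_taxonomy(rng, otu_ids, module_of)
    table = OtuTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        taxonomy=taxonomy,
        groups=pd.Series(group_labels, index=sample_ids, name="group"),
    )
    truth = GroundTruth(
        otu_module=module_of, planted_hubs=hubs, planted_connectors=connectors
    )
    return table, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """TSV with columns otu_id, module, is_hub, is_connector."""
    rows = [
        {
            "otu_id": o,
            "module": truth.otu_module[o],
            "is_hub": o in truth.planted_hubs,
            "is_connector": o in truth.planted_connectors,
        }
        for o in sorted(truth.otu_module)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"module": str})
    otu_module: dict[str, object] = {}
    hubs, conns = set(), set()
    for _, row in df.iterrows():
        m = row["module"]
        otu_module[row["otu_id"]] = "background" if m == "background" else int(m)
        if row["is_hub"]:
            hubs.add(row["otu_id"])
        if row["is_connector"]:
            conns.add(row["otu_id"])
    return GroundTruth(
        otu_module=otu_module, planted_hubs=hubs, planted_connectors=conns
    )
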