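"""Reading and writing OTU tables, sample metadata, and networks.

Canonical on-disk formats are plain tab-separated text:

* OTU table — rows are OTUs, columns are samples, plus a final
  ``taxonomy`` column holding a semicolon-separated lineage.  QIIME-style
  rank prefixes (``k__``, ``p__``, ...) are tolerated and stripped.
* sample metadata — two columns, ``sample_id`` and ``group``.
* networks — GraphML (with all node/edge attributes) or a simple edge
  list (``source  target  rho  p  sign``).

Relative abundances are always recomputed from counts downstream; they
are never read from a file, which avoids normalisation-dialect bugs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

#: The seven taxonomy ranks used throughout; shorter lineages are padded
#: with "unknown".
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class OtuTableError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass
class OtuTable:
    """An integer count matrix (samples x OTUs) with sample group labels
    and a 7-rank taxonomy lineage per OTU.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id.
    taxonomy
        DataFrame indexed by OTU id with the columns of :data:`RANKS`.
    groups
        Series mapping sample id to group label.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise OtuTableError(f"duplicate sample id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise OtuTableError(f"duplicate OTU id: {dup!r}")
        missing = self.counts.index.difference(self.groups.index)
        if len(missing):
            raise OtuTableError(
                f"sample {missing[0]!r} has no group in the metadata"
            )
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise OtuTableError(f"OTU {missing_tax[0]!r} has no taxonomy entry")
        if (self.counts.values < 0).any():
            raise OtuTableError("negative counts are not allowed")
        # align to the count matrix, preserving its order
        self.groups = self.groups.loc[self.counts.index]
        self.taxonomy = self.taxonomy.loc[self.counts.columns, list(RANKS)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def subset_group(self, group: str) -> "OtuTable":
        """Restrict to the samples of one group."""
        if group not in set(self.groups):
            raise OtuTableError(f"unknown group: {group!r}")
        keep = self.groups.index[self.groups == group]
        return OtuTable(
            counts=self.counts.loc[keep],
            taxonomy=self.taxonomy,
            groups=self.groups.loc[keep],
        )

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return tuple(self.taxonomy.loc[otu_id])


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-separated lineage into 7 ranks.

    QIIME prefixes like ``g__`` are stripped; empty ranks become
    ``"unknown"``; lineages shorter than 7 ranks are padded.  Labels such
    as ``no_rank`` or ``uncultured`` are kept verbatim.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    ranks = []
    for p in parts[: len(RANKS)]:
        p = _RANK_PREFIX.sub("", p).strip()
        ranks.append(p if p else "unknown")
    while len(ranks) < len(RANKS):
        ranks.append("unknown")
    return tuple(ranks)


def read_otu_table(table_path: str | Path, metadata_path: str | Path) -> OtuTable:
    """Read an OTU table TSV plus a sample->group metadata TSV.

    The table has OTU rows, sample columns and a final ``taxonomy``
    column; the metadata has columns ``sample_id`` and ``group``.
    """
    raw = pd.read_csv(table_path, sep="\t", index_col=0, dtype=str)
    if "taxonomy" not in raw.columns:
        raise OtuTableError(f"{table_path}: no 'taxonomy' column")
    tax_col = raw["taxonomy"]
    count_cols = [c for c in raw.columns if c != "taxonomy"]
    counts = raw[count_cols]
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        otu, sample = bad[bad].index[0]
        raise OtuTableError(
            f"non-numeric count at OTU {otu!r}, sample {sample!r}"
        )
    if ((numeric % 1) != 0).any().any():
        bad = ((numeric % 1) != 0).stack()
        otu, sample = bad[bad].index[0]
        raise OtuTableError(
            f"non-integer count at OTU {otu!r}, sample {sample!r}"
        )
    counts = numeric.astype("int64").T  # -> samples x OTUs
    counts.index.name = None
    counts.columns.name = None

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise OtuTableError(f"{metadata_path}: missing column {col!r}")
    groups = pd.Series(
        meta["group"].values, index=meta["sample_id"].values, name="group"
    )
    taxonomy = pd.DataFrame(
        [parse_lineage(v) for v in tax_col],
        index=tax_col.index,
        columns=list(RANKS),
    )
    return OtuTable(counts=counts, taxonomy=taxonomy, groups=groups)


def write_otu_table(
    table: OtuTable, table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the OTU table and metadata in the formats read back by
    :func:`read_otu_table` (lossless round-trip)."""
    prefixes = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
    out = table.counts.T.copy()
    out["taxonomy"] = [
        ";".join(p + r for p, r in zip(prefixes, table.taxonomy.loc[otu]))
        for otu in out.index
    ]
    out.index.name = "otu_id"
    out.to_csv(table_path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": table.groups.index, "group": table.groups.values}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or a TSV edge list.

    GraphML keeps every node attribute (taxonomy ranks, abundance class,
    group means, module id if assigned) and edge attribute (rho, p,
    sign).  The edge list holds ``source, target, rho, p, sign``.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist":
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]).to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path)
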