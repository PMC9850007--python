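"""End-to-end orchestration: per-group networks, the combined network,
module/role/keystone reports and pairwise network dissimilarities.

One :class:`RunConfig` (optionally loaded from YAML) drives the whole
analysis.  Every stage logs its input sizes and thresholds to
``run.log`` (messages only, no timestamps, so repeated runs with the
same config are byte-identical).

Outputs written by :func:`run_all` into the output directory::

    table1.tsv          per-network summary (nodes, edges, signs, rare/
                        abundant node fractions, modularity)
    modules.tsv         node -> module assignment of the combined network
    module_composition_phylum.tsv
    roles.tsv           per-node centralities, Zi/Pi, role, keystone flag
    crosstab.tsv        role x abundance-class counts and percentages
    keystones.tsv       keystone OTUs per network
    ternary.tsv         per-OTU group-mean abundances on the 3-group simplex
    dissimilarity.tsv   pairwise shared/unique edge counts and beta_w
    networks/<name>.graphml
    run.log
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from ._utils import pct
from .abundance import relative_abundance, select_top_otus, ternary_coordinates
from .community import ModulePartition, detect_modules, module_composition
from .conet import build_network, edge_sign_summary, spearman_matrix
from .io import OtuTable, read_otu_table, write_network
from .netbeta import network_dissimilarity
from .roles import role_abundance_crosstab, role_table
from .topology import node_topology

logger = logging.getLogger("coocnet")

#: Column order of the per-network summary table.
SUMMARY_COLUMNS = [
    "network", "n_nodes", "n_edges", "n_positive", "n_negative",
    "pct_positive", "pct_rare", "pct_abundant", "modularity",
]


@dataclass
class RunConfig:
    """All tunable parameters of a full analysis run."""

    table: str = ""
    metadata: str = ""
    output_dir: str = "results"
    groups: list[str] = field(default_factory=list)  # empty -> all groups
    top_n: int = 1000
    rho_threshold: float = 0.6
    p_threshold: float = 0.05
    min_major_size: int = 10
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    keystone_degree_min: int = 50
    keystone_betweenness_max: float = 5000.0
    rare_threshold: float = 1e-4
    abundant_threshold: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.rho_threshold <= 1 and 0 < self.p_threshold <= 1):
            raise ValueError("correlation thresholds must lie in (0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0 <= self.rare_threshold <= self.abundant_threshold <= 1):
            raise ValueError("abundance thresholds must satisfy 0 <= rare <= abundant <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def build_group_network(
    config: RunConfig, table: OtuTable, group: str | None
) -> tuple[nx.Graph, "pd.Series"]:
    """Build the co-occurrence network for one group (or the pooled
    table when ``group`` is None).  Returns the network and the
    abundance classes used for its nodes."""
    sub = table if group is None else table.subset_group(group)
    profile = relative_abundance(sub)
    top = select_top_otus(profile, config.top_n)
    logger.info(
        "network %s: %d samples, %d OTUs, top %d selected",
        group or "combined", len(sub.sample_ids), len(sub.otu_ids), len(top),
    )
    corr = spearman_matrix(sub, top)
    net = build_network(
        corr,
        profile=profile,
        rho_threshold=config.rho_threshold,
        p_threshold=config.p_threshold,
        taxonomy=sub.taxonomy,
    )
    net.graph["name"] = group or "combined"
    logger.info(
        "network %s: %d nodes, %d edges (|rho| >= %g, p <= %g)",
        group or "combined", net.number_of_nodes(), net.number_of_edges(),
        config.rho_threshold, config.p_threshold,
    )
    return net, profile.abundance_class


def summarize_network(
    config: RunConfig, name: str, net: nx.Graph
) -> tuple[dict, ModulePartition | None]:
    """One summary row (the per-network report schema) plus the module
    partition used for its modularity value."""
    n_edges, n_pos, n_neg, pct_pos = edge_sign_summary(net)
    n_nodes = net.number_of_nodes()
    classes = [d.get("abundance_class") for _, d in net.nodes(data=True)]
    part = None
    if n_edges > 0:
        part = detect_modules(net, min_major_size=config.min_major_size,
                              seed=config.seed)
    row = {
        "network": name,
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pct_positive": pct_pos,
        "pct_rare": pct(sum(c == "rare" for c in classes), n_nodes),
        "pct_abundant": pct(sum(c == "abundant" for c in classes), n_nodes),
        "modularity": round(part.modularity_q, 3) if part else float("nan"),
    }
    return row, part


def run_group_analysis(config: RunConfig, table: OtuTable, group: str) -> dict:
    """Build one group's network and return its summary row."""
    net, _ = build_group_network(config, table, group)
    row, _ = summarize_network(config, group, net)
    return row


def run_all(config: RunConfig, table: OtuTable | None = None) -> dict:
    """Run the full analysis and write every report table.

    Returns a dict with the in-memory results (networks, summary frame,
    partition, role table, comparisons) for programmatic use.
    """
    config.validate()
    out = Path(config.output_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if table is None:
            table = read_otu_table(config.table, config.metadata)
        groups = config.groups or table.group_names
        logger.info(
            "input: %d samples, %d OTUs, groups %s",
            len(table.sample_ids), len(table.otu_ids), ",".join(groups),
        )

        networks: dict[str, nx.Graph] = {}
        rows = []
        net, _ = build_group_network(config, table, None)
        networks["combined"] = net
        row, part = summarize_network(config, "combined", net)
        rows.append(row)
        for g in groups:
            gnet, _ = build_group_network(config, table, g)
            networks[g] = gnet
            grow, _ = summarize_network(config, g, gnet)
            rows.append(grow)
        summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
        summary.to_csv(out / "table1.tsv", sep="\t", index=False)

        combined = networks["combined"]
        if part is None:
            raise ValueError("combined network has no edges")
        modules_df = pd.DataFrame(
            {
                "otu_id": list(part.assignment),
                "module": [part.assignment[n] for n in part.assignment],
                "major": [
                    part.assignment[n] in part.major_modules
                    for n in part.assignment
                ],
            }
        ).sort_values(["module", "otu_id"])
        modules_df.to_csv(out / "modules.tsv", sep="\t", index=False)
        composition = module_composition(combined, part, rank="phylum")
        composition.to_csv(out / "module_composition_phylum.tsv", sep="\t",
                           index=False)

        topo = node_topology(combined)
        roles = role_table(
            combined, part, topo,
            zi_threshold=config.zi_threshold,
            pi_threshold=config.pi_threshold,
            degree_min=config.keystone_degree_min,
            betweenness_max=config.keystone_betweenness_max,
        )
        roles.to_csv(out / "roles.tsv", sep="\t", float_format="%.6g")
        crosstab = role_abundance_crosstab(roles)
        crosstab.to_csv(out / "crosstab.tsv", sep="\t", index=False)
        role_counts = roles["role"].value_counts()
        for role in ("peripheral", "connector", "module_hub", "network_hub"):
            logger.info(
                "role %s: %d nodes (%.2f%%)", role,
                role_counts.get(role, 0), 100 * role_counts.get(role, 0) / len(roles),
            )

        keystone_rows = []
        for name, network in networks.items():
            ntopo = topo if name == "combined" else node_topology(network)
            from .roles import keystone_flags

            ks = keystone_flags(
                ntopo, config.keystone_degree_min, config.keystone_betweenness_max
            )
            logger.info("network %s: %d keystone OTUs", name, len(ks))
            for otu in sorted(ks):
                keystone_rows.append(
                    {
                        "network": name,
                        "otu_id": otu,
                        "degree": int(ntopo.loc[otu, "degree"]),
                        "betweenness": float(ntopo.loc[otu, "betweenness"]),
                        "abundance_class": network.nodes[otu].get(
                            "abundance_class", "unknown"
                        ),
                    }
                )
        pd.DataFrame(
            keystone_rows,
            columns=["network", "otu_id", "degree", "betweenness", "abundance_class"],
        ).to_csv(out / "keystones.tsv", sep="\t", index=False, float_format="%.6g")

        ternary = None
        if len(table.group_names) == 3:
            ternary = ternary_coordinates(table, list(combined.nodes))
            tern_out = ternary.copy()
            tern_out.insert(
                0, "module", [part.assignment[o] for o in tern_out.index]
            )
            tern_out.index.name = "otu_id"
            tern_out.to_csv(out / "ternary.tsv", sep="\t", float_format="%.6g")

        comparisons = []
        names = list(networks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if (
                    networks[a].number_of_edges() == 0
                    or networks[b].number_of_edges() == 0
                ):
                    continue
                cmp = network_dissimilarity(networks[a], networks[b])
                comparisons.append(
                    {
                        "network_a": a,
                        "network_b": b,
                        "shared_edges": cmp.shared_edges,
                        "unique_to_a": cmp.unique_to_first,
                        "unique_to_b": cmp.unique_to_second,
                        "dissimilarity": round(cmp.dissimilarity, 6),
                    }
                )
        pd.DataFrame(
            comparisons,
            columns=["network_a", "network_b", "shared_edges", "unique_to_a",
                     "unique_to_b", "dissimilarity"],
        ).to_csv(out / "dissimilarity.tsv", sep="\t", index=False)

        for name, network in networks.items():
            if network.number_of_nodes() == 0:
                continue
            if name == "combined":
                for node, m in part.assignment.items():
                    network.nodes[node]["module"] = m
            write_network(network, out / "networks" / f"{name}.graphml")

        return {
            "networks": networks,
            "summary": summary,
            "partition": part,
            "roles": roles,
            "crosstab": crosstab,
            "ternary": ternary,
            "comparisons": comparisons,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
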