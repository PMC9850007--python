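"""Zi-Pi node roles and keystone taxa.

Within-module connectivity Zi is the z-score of a node's number of
links into its own module, standardized over that module's members
(population standard deviation; a module where everyone has the same
within-module degree gets Zi = 0 for all members).  Among-module
connectivity (participation coefficient) is

    Pi = 1 - sum_m (k_im / k_i)^2

over all modules m, with k_i the node's total degree.

Roles partition the (Zi, Pi) plane:

* network hub — Zi > 2.5 and Pi > 0.62
* module hub  — Zi > 2.5 and Pi <= 0.62
* connector   — Zi <= 2.5 and Pi > 0.62
* peripheral  — Zi <= 2.5 and Pi <= 0.62

Keystone taxa are nodes with high degree (> 50) and low raw betweenness
(< 5000), i.e. strongly connected nodes that are not mere bridges.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from ._utils import pct
from .community import ModulePartition

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
KEYSTONE_DEGREE_MIN = 50
KEYSTONE_BETWEENNESS_MAX = 5000.0

ROLES = ("network_hub", "module_hub", "connector", "peripheral")


def zi_pi(net: nx.Graph, part: ModulePartition) -> pd.DataFrame:
    """Within- (Zi) and among-module (Pi) connectivity per node."""
    missing = set(net.nodes) - set(part.assignment)
    if missing:
        raise ValueError(f"partition misses nodes, e.g. {sorted(missing)[0]!r}")
    assignment = part.assignment
    nodes = list(net.nodes)

    # links from each node into each module
    module_links: dict[str, dict[int, int]] = {v: {} for v in nodes}
    for u, v in net.edges:
        mu, mv = assignment[u], assignment[v]
        module_links[u][mv] = module_links[u].get(mv, 0) + 1
        module_links[v][mu] = module_links[v].get(mu, 0) + 1

    kappa_own = {v: module_links[v].get(assignment[v], 0) for v in nodes}
    by_module: dict[int, list[str]] = {}
    for v in nodes:
        by_module.setdefault(assignment[v], []).append(v)

    zi: dict[str, float] = {}
    for members in by_module.values():
        vals = [kappa_own[v] for v in members]
        mean = sum(vals) / len(vals)
        var = sum((x - mean) ** 2 for x in vals) / len(vals)
        sd = math.sqrt(var)
        for v in members:
            zi[v] = 0.0 if sd == 0 else (kappa_own[v] - mean) / sd

    pi: dict[str, float] = {}
    for v in nodes:
        k = net.degree(v)
        pi[v] = 1.0 - sum((c / k) ** 2 for c in module_links[v].values())

    return pd.DataFrame({"zi": pd.Series(zi), "pi": pd.Series(pi)}).loc[nodes]


def classify_role(
    zi: float, pi: float,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> str:
    """Role of a node in the (Zi, Pi) plane (hub cutoffs strict >)."""
    hub = zi > zi_threshold
    spread = pi > pi_threshold
    if hub:
        return "network_hub" if spread else "module_hub"
    return "connector" if spread else "peripheral"


def keystone_flags(
    topo: pd.DataFrame,
    degree_min: int = KEYSTONE_DEGREE_MIN,
    betweenness_max: float = KEYSTONE_BETWEENNESS_MAX,
) -> set[str]:
    """Nodes with degree strictly above ``degree_min`` and raw
    betweenness strictly below ``betweenness_max``."""
    mask = (topo["degree"] > degree_min) & (topo["betweenness"] < betweenness_max)
    return set(topo.index[mask])


def role_table(
    net: nx.Graph,
    part: ModulePartition,
    topo: pd.DataFrame,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
    degree_min: int = KEYSTONE_DEGREE_MIN,
    betweenness_max: float = KEYSTONE_BETWEENNESS_MAX,
) -> pd.DataFrame:
    """Assemble the per-node role records: centralities, Zi/Pi, role,
    keystone flag, module id and abundance class."""
    zp = zi_pi(net, part)
    keystones = keystone_flags(topo, degree_min, betweenness_max)
    rows = []
    for node in net.nodes:
        rows.append(
            {
                "otu_id": node,
                "module": part.assignment[node],
                "degree": int(topo.loc[node, "degree"]),
                "betweenness": float(topo.loc[node, "betweenness"]),
                "closeness": float(topo.loc[node, "closeness"]),
                "eigenvector": float(topo.loc[node, "eigenvector"]),
                "zi": float(zp.loc[node, "zi"]),
                "pi": float(zp.loc[node, "pi"]),
                "role": classify_role(
                    zp.loc[node, "zi"], zp.loc[node, "pi"],
                    zi_threshold, pi_threshold,
                ),
                "keystone": node in keystones,
                "abundance_class": net.nodes[node].get("abundance_class", "unknown"),
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


def role_abundance_crosstab(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-role percentages of abundance classes per role.

    ``records`` needs columns ``role`` and ``abundance_class``; the
    percentage within each role sums to 100 (half-up, 2 decimals).
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["role", "abundance_class", "count", "pct"])
    rows = []
    for role, sub in records.groupby("role"):
        total = len(sub)
        for klass, n in sub["abundance_class"].value_counts().items():
            rows.append(
                {
                    "role": role,
                    "abundance_class": klass,
                    "count": int(n),
                    "pct": pct(n, total),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["role", "abundance_class"])
        .reset_index(drop=True)
    )
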