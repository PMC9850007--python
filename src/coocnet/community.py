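"""Module detection, Newman modularity, and module composition.

Modularity of a partition is Newman's

    Q = sum_s [ l_s / L - (d_s / 2L)^2 ]

with L the total number of edges, l_s the number of edges inside module
s and d_s the summed degree of its members — unweighted and blind to the
correlation sign of an edge.

Module detection is greedy agglomerative modularity maximization (CNM)
followed by one pass of local single-node moves, which is deterministic
for a fixed input graph.  Detected modules are relabeled 1..K by
decreasing size (ties by smallest member id); "major" modules are those
with more than ``min_major_size`` nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import RANKS


@dataclass
class ModulePartition:
    """A node -> module assignment with its modularity score.

    Module ids are contiguous 1..K, ordered by decreasing module size.
    """

    assignment: dict[str, int]
    modularity_q: float
    major_modules: list[int]
    min_major_size: int
    sizes: dict[int, int] = field(default_factory=dict)

    def members(self, module_id: int) -> list[str]:
        return sorted(n for n, m in self.assignment.items() if m == module_id)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


def modularity(net: nx.Graph, assignment: dict[str, int]) -> float:
    """Newman's Q for an explicit assignment covering every node."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses nodes, e.g. {sorted(missing)[0]!r}")
    L = net.number_of_edges()
    if L == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    inner: dict[int, int] = {}
    deg: dict[int, int] = {}
    for node, d in net.degree():
        m = assignment[node]
        deg[m] = deg.get(m, 0) + d
    for u, v in net.edges:
        if assignment[u] == assignment[v]:
            m = assignment[u]
            inner[m] = inner.get(m, 0) + 1
    q = 0.0
    for m in set(assignment[n] for n in net.nodes):
        q += inner.get(m, 0) / L - (deg.get(m, 0) / (2.0 * L)) ** 2
    return q


def _local_refinement(
    net: nx.Graph, assignment: dict[str, int]
) -> dict[str, int]:
    """One pass of single-node moves to adjacent modules, accepting the
    best strictly-positive modularity gain (ties -> smallest module id).

    Uses the standard O(deg) gain formula instead of recomputing Q.
    """
    L = net.number_of_edges()
    deg = dict(net.degree())
    deg_sum: dict[int, int] = {}
    for node, d in deg.items():
        m = assignment[node]
        deg_sum[m] = deg_sum.get(m, 0) + d
    assignment = dict(assignment)
    for node in sorted(net.nodes):
        current = assignment[node]
        links: dict[int, int] = {}
        for nbr in net.neighbors(node):
            m = assignment[nbr]
            links[m] = links.get(m, 0) + 1
        k = deg[node]
        best_gain, best_mod = 1e-12, None
        for m in sorted(links):
            if m == current:
                continue
            # gain of moving `node` from `current` to `m`
            gain = (
                (links.get(m, 0) - links.get(current, 0)) / L
                - k * (deg_sum.get(m, 0) - (deg_sum.get(current, 0) - k))
                / (2.0 * L * L)
            )
            if gain > best_gain:
                best_gain, best_mod = gain, m
        if best_mod is not None:
            assignment[node] = best_mod
            deg_sum[current] -= k
            deg_sum[best_mod] = deg_sum.get(best_mod, 0) + k
    return assignment


def _relabel(assignment: dict[str, int]) -> dict[str, int]:
    """Contiguous 1..K ids sorted by size descending, ties by smallest
    member id."""
    groups: dict[int, list[str]] = {}
    for node, m in assignment.items():
        groups.setdefault(m, []).append(node)
    ordered = sorted(groups.values(), key=lambda ns: (-len(ns), min(ns)))
    out: dict[str, int] = {}
    for new_id, members in enumerate(ordered, start=1):
        for node in members:
            out[node] = new_id
    return out


def detect_modules(
    net: nx.Graph, min_major_size: int = 10, seed: int = 0
) -> ModulePartition:
    """Detect modules by greedy modularity maximization plus one local
    refinement pass.

    ``seed`` is accepted for interface stability; the procedure itself
    is deterministic for a fixed graph.  The result never scores below
    the trivial all-in-one partition (Q = 0).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.number_of_edges() == 0:
        raise ValueError("network has no edges")
    communities = nx.community.greedy_modularity_communities(net)
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    assignment = _local_refinement(net, assignment)
    if modularity(net, assignment) < 0.0:
        assignment = {n: 0 for n in net.nodes}
    assignment = _relabel(assignment)
    q = modularity(net, assignment)
    sizes: dict[int, int] = {}
    for m in assignment.values():
        sizes[m] = sizes.get(m, 0) + 1
    major = [m for m in sorted(sizes) if sizes[m] > min_major_size]
    return ModulePartition(
        assignment=assignment,
        modularity_q=q,
        major_modules=major,
        min_major_size=min_major_size,
        sizes=sizes,
    )


def module_composition(
    net: nx.Graph, part: ModulePartition, rank: str = "phylum"
) -> pd.DataFrame:
    """Node counts and fractions per (module, taxon) at one rank.

    Unknown taxa are pooled under ``unclassified``; fractions sum to 1
    within each module.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    rows = []
    counts: dict[tuple[int, str], int] = {}
    totals: dict[int, int] = {}
    for node, m in part.assignment.items():
        taxon = str(net.nodes[node].get(rank, "unknown"))
        if taxon in ("unknown", "", "nan"):
            taxon = "unclassified"
        counts[(m, taxon)] = counts.get((m, taxon), 0) + 1
        totals[m] = totals.get(m, 0) + 1
    for (m, taxon), c in sorted(counts.items()):
        rows.append(
            {
                "module": m,
                "taxon": taxon,
                "count": c,
                "fraction": c / totals[m],
            }
        )
    return pd.DataFrame(rows, columns=["module", "taxon", "count", "fraction"])
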