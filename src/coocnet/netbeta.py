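"""Dissimilarity between two co-occurrence networks from their shared
and unique edges.

With a = shared edges, b = edges only in the first network and c =
edges only in the second, the Whittaker turnover index is

    beta_w = (a + b + c) / ((2a + b + c) / 2) - 1

which is 0 for identical edge sets and 1 for disjoint ones.  A Jaccard
distance variant, 1 - a/(a+b+c), is available as an alternative.  Edge
identity is by unordered OTU-id pair only — the sign and magnitude of
the underlying correlations are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass
class NetComparison:
    """Shared/unique edge counts and a dissimilarity index."""

    shared_edges: int
    unique_to_first: int
    unique_to_second: int
    dissimilarity: float
    metric: str = "whittaker"


def _edge_set(net: nx.Graph) -> set[frozenset]:
    return {frozenset((u, v)) for u, v in net.edges}


def network_dissimilarity(
    net1: nx.Graph, net2: nx.Graph, metric: str = "whittaker"
) -> NetComparison:
    """Compare the edge sets of two networks.

    ``metric`` is ``"whittaker"`` (default) or ``"jaccard"``.
    """
    if net1.number_of_edges() == 0 or net2.number_of_edges() == 0:
        raise ValueError("both networks must have at least one edge")
    e1, e2 = _edge_set(net1), _edge_set(net2)
    a = len(e1 & e2)
    b = len(e1 - e2)
    c = len(e2 - e1)
    if metric == "whittaker":
        d = (a + b + c) / ((2 * a + b + c) / 2.0) - 1.0
    elif metric == "jaccard":
        d = 1.0 - a / (a + b + c)
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return NetComparison(
        shared_edges=a,
        unique_to_first=b,
        unique_to_second=c,
        dissimilarity=d,
        metric=metric,
    )
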