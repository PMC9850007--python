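"""Node-level centralities and between-network feature comparisons.

Conventions
-----------
degree
    Number of incident edges.
betweenness
    Raw (unnormalized) count over unordered pairs (s, t) of the fraction
    of shortest s-t paths through the node.  Raw counts are used so that
    integer-valued cutoffs on betweenness (such as the keystone rule)
    are meaningful; the normalized value is emitted alongside.
closeness
    Component-corrected: ((n_c - 1)/(n - 1)) * ((n_c - 1) / sum of
    distances inside the node's component), which stays in [0, 1] on
    disconnected graphs.
eigenvector
    Power iteration on the (shifted) adjacency matrix of the full graph,
    uniform start vector, tight convergence tolerance, normalized so the maximum
    entry is 1.  On disconnected graphs nodes outside the dominant
    component get values near 0.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-13, max_iter: int = 20000
) -> dict[str, float]:
    """Max-normalized eigenvector centrality by deterministic power
    iteration.

    Iterates on A + I (same eigenvectors, strictly dominant leading
    eigenvalue, so bipartite graphs converge too).
    """
    nodes = list(net.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a @ x + x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.abs(nxt - x).max() < tol:
            x = nxt
            break
        x = nxt
    peak = x.max()
    if peak > 0:
        x = x / peak
    return {node: float(v) for node, v in zip(nodes, x)}


def node_topology(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness (raw and normalized), closeness and
    eigenvector centrality, indexed by node id."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(net.nodes)
    n = len(nodes)
    degree = dict(net.degree())
    betw = nx.betweenness_centrality(net, normalized=False)
    denom = (n - 1) * (n - 2) / 2.0
    betw_norm = {v: (betw[v] / denom if denom > 0 else 0.0) for v in nodes}
    close = nx.closeness_centrality(net, wf_improved=True)
    eig = eigenvector_centrality(net)
    return pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=int),
            "betweenness": pd.Series(betw),
            "betweenness_normalized": pd.Series(betw_norm),
            "closeness": pd.Series(close),
            "eigenvector": pd.Series(eig),
        }
    ).loc[nodes]


def _exact_mwu_pvalue(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of the
    C(n_a + n_b, n_a) group labelings (ties handled exactly)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    mean_u = na * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2.0
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def compare_feature(
    net_a_values, net_b_values, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U comparison of two node-feature distributions.

    Returns (U, p) for the first sample.  Uses full enumeration (exact
    even under ties) when both samples have <= 8 values and the
    tie-corrected, continuity-corrected normal approximation otherwise.
    One-sided alternatives fall back to the normal approximation.
    """
    a = np.asarray(list(net_a_values), dtype=float)
    b = np.asarray(list(net_b_values), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)
    if alternative == "two-sided" and len(a) <= 8 and len(b) <= 8:
        p = _exact_mwu_pvalue(a, b, u)
    else:
        _, p = stats.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
        p = float(p)
    return u, min(p, 1.0)


# ---------------------------------------------------------------------------
# brute-force references (used as independent oracles in the test suite)


def brute_force_centralities(net: nx.Graph) -> pd.DataFrame:
    """Reference centralities by explicit path enumeration and dense
    eigendecomposition; O(n!)-ish, for tiny graphs only."""
    nodes = list(net.nodes)
    n = len(nodes)
    dist = dict(nx.all_pairs_shortest_path_length(net))

    betw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        paths = list(nx.all_shortest_paths(net, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            betw[v] += through / len(paths)

    close = {}
    for v in nodes:
        reach = [d for u, d in dist[v].items() if u != v]
        n_c = len(reach) + 1
        if not reach or n == 1:
            close[v] = 0.0
        else:
            close[v] = ((n_c - 1) / (n - 1)) * ((n_c - 1) / sum(reach))

    a = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    w, vecs = np.linalg.eigh(a)
    lead = vecs[:, np.argmax(w)]
    lead = np.abs(lead)
    if lead.max() > 0:
        lead = lead / lead.max()
    eig = dict(zip(nodes, lead))

    return pd.DataFrame(
        {
            "degree": pd.Series(dict(net.degree()), dtype=int),
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(close),
            "eigenvector": pd.Series(eig),
        }
    ).loc[nodes]
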