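"""Spearman correlation matrices and signed co-occurrence networks.

Edges of the network are OTU pairs whose Spearman rank correlation is
both strong (|rho| >= 0.6 by default, inclusive) and significant
(p <= 0.05 by default, inclusive).  The graph is undirected and
unweighted for all downstream topology; rho, p and the correlation sign
are kept as edge attributes only.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .abundance import AbundanceProfile
from .io import RANKS, OtuTable


@dataclass
class CorrelationSet:
    """Pairwise Spearman rho and p-value matrices over a set of OTUs."""

    otus: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.otus.index(a), self.otus.index(b)
        return float(self.rho[i, j]), float(self.p[i, j])


def _t_approx_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values from t = rho * sqrt((n-2) / (1-rho^2)) on
    n - 2 degrees of freedom; |rho| = 1 maps to p = 0."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.clip(p, 0.0, 1.0)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho of one pair: Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_exact_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p-value for Spearman's rho.

    Enumerates all n! orderings of ``y`` (n <= 10), so it serves as an
    independent check of the t-approximation, which can deviate from the
    exact null by up to ~0.1 at n = 5.
    """
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p-value limited to n <= 10")
    observed = abs(spearman_rho(x, y))
    y = np.asarray(y)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(spearman_rho(x, y[list(perm)]))
        if r >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman_matrix(
    table: OtuTable, otus: list[str] | None = None, method: str = "t"
) -> CorrelationSet:
    """All pairwise Spearman correlations among the given OTUs.

    Ranks use average-rank tie handling.  Constant (all-tied) OTU
    vectors have no defined rank correlation; their pairs are recorded
    as rho = 0, p = 1 with a warning, so they can never create edges.

    ``method`` is ``"t"`` (default, the conventional t-approximation) or
    ``"exact"`` (full permutation null, only for <= 10 samples).
    """
    if otus is None:
        otus = table.otu_ids
    unknown = set(otus) - set(table.otu_ids)
    if unknown:
        raise ValueError(f"OTUs not in table: {sorted(unknown)[:3]}")
    x = table.counts[list(otus)].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlations, got {n}")

    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        bad = [o for o, c in zip(otus, constant) if c]
        warnings.warn(
            f"{len(bad)} constant OTU vector(s) (e.g. {bad[0]!r}): "
            "rho set to 0, p to 1 for their pairs",
            stacklevel=2,
        )
    centred = ranks - ranks.mean(axis=0)
    denom = np.where(constant, 1.0, sd * math.sqrt(n))
    z = centred / denom
    rho = np.clip(z.T @ z, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    if method == "t":
        p = _t_approx_pvalues(rho, n)
    elif method == "exact":
        p = np.ones_like(rho)
        for i in range(len(otus)):
            for j in range(i + 1, len(otus)):
                if not (constant[i] or constant[j]):
                    p[i, j] = p[j, i] = spearman_exact_pvalue(x[:, i], x[:, j])
    else:
        raise ValueError(f"unknown method: {method!r}")
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)
    return CorrelationSet(otus=list(otus), rho=rho, p=p, n_samples=n)


def build_network(
    corr: CorrelationSet,
    profile: AbundanceProfile | None = None,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.05,
    fdr: bool = False,
    taxonomy=None,
) -> nx.Graph:
    """Threshold a correlation set into a signed co-occurrence network.

    Edges are exactly the pairs with |rho| >= ``rho_threshold`` and
    p <= ``p_threshold`` (both inclusive); edge ``sign`` is ``positive``
    iff rho > 0.  OTUs left without any edge are dropped.  Node
    attributes (abundance class, group means, taxonomy ranks) are copied
    from ``profile`` / ``taxonomy`` when given.

    ``fdr=True`` applies a Benjamini–Hochberg correction to the p-values
    before thresholding; it is off by default.
    """
    if not (0 < rho_threshold <= 1) or not (0 < p_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    otus = corr.otus
    m = len(otus)
    p = corr.p
    if fdr:
        iu = np.triu_indices(m, k=1)
        adj = stats.false_discovery_control(p[iu], method="bh")
        p = p.copy()
        p[iu] = adj
        p[(iu[1], iu[0])] = adj

    net = nx.Graph()
    net.graph["rho_threshold"] = rho_threshold
    net.graph["p_threshold"] = p_threshold
    iu, ju = np.nonzero(
        np.triu((np.abs(corr.rho) >= rho_threshold) & (p <= p_threshold), k=1)
    )
    for i, j in zip(iu, ju):
        rho = float(corr.rho[i, j])
        net.add_edge(
            otus[i],
            otus[j],
            rho=rho,
            p=float(p[i, j]),
            sign="positive" if rho > 0 else "negative",
        )
    for node in net.nodes:
        if profile is not None:
            net.nodes[node]["abundance_class"] = profile.abundance_class[node]
            net.nodes[node]["overall_mean"] = float(profile.overall_mean[node])
            for g in profile.group_mean.columns:
                net.nodes[node][f"group_mean_{g}"] = float(
                    profile.group_mean.loc[node, g]
                )
        if taxonomy is not None:
            for rank in RANKS:
                net.nodes[node][rank] = str(taxonomy.loc[node, rank])
    return net


def edge_sign_summary(net: nx.Graph) -> tuple[int, int, int, float]:
    """(n_edges, n_positive, n_negative, pct_positive) of a network.

    The percentage is half-up rounded to 2 decimals; an empty network
    reports NaN.
    """
    from ._utils import pct

    signs = [d["sign"] for _, _, d in net.edges(data=True)]
    n_edges = len(signs)
    n_pos = sum(s == "positive" for s in signs)
    n_neg = n_edges - n_pos
    return n_edges, n_pos, n_neg, pct(n_pos, n_edges)
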