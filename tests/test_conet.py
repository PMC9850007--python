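import warnings

import numpy as np
import pytest
from scipy import stats

from coocnet.abundance import relative_abundance
from coocnet.conet import (
    CorrelationSet,
    build_network,
    edge_sign_summary,
    spearman_exact_pvalue,
    spearman_matrix,
)
from conftest import make_table


def manual_spearman(x, y):
    """Independent reference: explicit average ranks + Pearson on ranks."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i: j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanMatrix:
    def test_perfect_monotone(self):
        table = make_table(np.array([[1, 10], [2, 20], [3, 21], [4, 40], [5, 41]]))
        corr = spearman_matrix(table)
        assert corr.rho[0, 1] == pytest.approx(1.0)
        assert corr.p[0, 1] == 0.0

    def test_perfect_antitone(self):
        table = make_table(np.array([[1, 50], [2, 40], [3, 30], [4, 20], [5, 10]]))
        corr = spearman_matrix(table)
        assert corr.rho[0, 1] == pytest.approx(-1.0)

    def test_reference_pair_against_permutation_null(self):
        # oracle: the rank formula gives rho = 1 - 6*4/120 = 0.8 and the
        # exhaustive 5! permutation p differs from the t-approximation
        # by less than the documented ~0.1 at n = 5
        x = np.array([1, 2, 3, 4, 5])
        y = np.array([2, 1, 4, 3, 5])
        assert manual_spearman(x, y) == pytest.approx(0.8)
        table = make_table(np.column_stack([x, y]))
        corr = spearman_matrix(table)
        assert corr.rho[0, 1] == pytest.approx(0.8, abs=1e-12)
        p_exact = spearman_exact_pvalue(x, y)
        assert p_exact == pytest.approx(8.0 / 60.0, abs=1e-12)
        assert abs(corr.p[0, 1] - p_exact) < 0.1

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            counts = rng.integers(0, 40, size=(10, 10))
            if (counts.max(axis=0) == counts.min(axis=0)).any():
                continue
            table = make_table(counts)
            corr = spearman_matrix(table)
            for i in range(10):
                for j in range(i + 1, 10):
                    ref = manual_spearman(counts[:, i], counts[:, j])
                    assert corr.rho[i, j] == pytest.approx(ref, abs=1e-12)
                    sp = stats.spearmanr(counts[:, i], counts[:, j])
                    assert corr.rho[i, j] == pytest.approx(sp.statistic, abs=1e-12)
                    assert corr.p[i, j] == pytest.approx(sp.pvalue, abs=1e-9)

    def test_constant_vector_convention(self):
        table = make_table(np.array([[3, 1], [3, 2], [3, 3], [3, 4]]))
        with pytest.warns(UserWarning, match="constant"):
            corr = spearman_matrix(table)
        assert corr.rho[0, 1] == 0.0
        assert corr.p[0, 1] == 1.0

    def test_too_few_samples(self):
        table = make_table(np.array([[1, 2], [3, 4], [5, 6]]))
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(table)


def _corr_set(rho_pairs, n=100):
    """CorrelationSet over 3 OTUs with given (rho01, p01, rho02, p02, ...)."""
    otus = ["A", "B", "C"]
    rho = np.eye(3)
    p = np.zeros((3, 3))
    (r1, p1), (r2, p2), (r3, p3) = rho_pairs
    rho[0, 1] = rho[1, 0] = r1; p[0, 1] = p[1, 0] = p1
    rho[0, 2] = rho[2, 0] = r2; p[0, 2] = p[2, 0] = p2
    rho[1, 2] = rho[2, 1] = r3; p[1, 2] = p[2, 1] = p3
    return CorrelationSet(otus=otus, rho=rho, p=p, n_samples=n)


class TestBuildNetwork:
    def test_inclusive_thresholds(self):
        corr = _corr_set([(0.6, 0.05), (0.59, 0.001), (-0.7, 0.2)])
        net = build_network(corr)
        assert set(map(frozenset, net.edges)) == {frozenset(("A", "B"))}
        assert net.edges["A", "B"]["sign"] == "positive"

    def test_negative_edge_sign(self):
        corr = _corr_set([(-0.8, 0.001), (0.0, 1.0), (0.0, 1.0)])
        net = build_network(corr)
        assert net.edges["A", "B"]["sign"] == "negative"

    def test_no_pair_passing_gives_empty_network(self):
        corr = _corr_set([(0.5, 0.2), (0.1, 0.9), (-0.2, 0.5)])
        net = build_network(corr)
        assert net.number_of_nodes() == 0

    def test_isolated_nodes_dropped(self):
        corr = _corr_set([(0.9, 0.001), (0.0, 1.0), (0.0, 1.0)])
        net = build_network(corr)
        assert set(net.nodes) == {"A", "B"}

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=(12, 8))
        table = make_table(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = spearman_matrix(table)
        previous = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            edges = set(map(frozenset, build_network(corr, rho_threshold=thr).edges))
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_node_attributes_copied_from_profile(self):
        table = make_table(
            np.array([[60, 40], [55, 45], [50, 50], [45, 55], [62, 38]])
        )
        profile = relative_abundance(table)
        corr = spearman_matrix(table)
        net = build_network(corr, profile=profile, rho_threshold=0.5,
                            p_threshold=1.0, taxonomy=table.taxonomy)
        assert net.nodes["OTU0"]["abundance_class"] == "abundant"
        assert net.nodes["OTU0"]["kingdom"] == "Bacteria"


class TestEdgeSignSummary:
    @pytest.mark.parametrize(
        "n_edges, n_pos, expected",
        [(4844, 4818, 99.46), (3379, 3377, 99.94), (5502, 5499, 99.95)],
    )
    def test_positive_percentages(self, n_edges, n_pos, expected):
        import networkx as nx

        net = nx.Graph()
        for i in range(n_pos):
            net.add_edge(f"p{i}", f"q{i}", sign="positive")
        for i in range(n_edges - n_pos):
            net.add_edge(f"m{i}", f"n{i}", sign="negative")
        total, pos, neg, pct_pos = edge_sign_summary(net)
        assert (total, pos, neg) == (n_edges, n_pos, n_edges - n_pos)
        assert pct_pos == expected

    def test_all_positive_is_100(self):
        import networkx as nx

        net = nx.Graph()
        net.add_edge("a", "b", sign="positive")
        assert edge_sign_summary(net)[3] == 100.0

    def test_empty_network_reports_nan(self):
        import networkx as nx

        n_edges, n_pos, n_neg, pct_pos = edge_sign_summary(nx.Graph())
        assert (n_edges, n_pos, n_neg) == (0, 0, 0)
        assert np.isnan(pct_pos)
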