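import itertools

import networkx as nx
import numpy as np
import pytest

from coocnet.community import (
    detect_modules,
    modularity,
    module_composition,
)
from conftest import random_graph


def brute_force_modularity(net, assignment):
    """Reference Q by direct edge counting."""
    L = net.number_of_edges()
    q = 0.0
    for module in set(assignment.values()):
        members = {n for n, m in assignment.items() if m == module}
        inside = sum(
            1 for u, v in net.edges if u in members and v in members
        )
        deg = sum(d for n, d in net.degree if n in members)
        q += inside / L - (deg / (2 * L)) ** 2
    return q


def all_partitions(items):
    """Every set partition of `items` (Bell number many)."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [head]] + partition[i + 1:]
        yield partition + [[head]]


def exhaustive_best_q(net):
    best = -1.0
    for partition in all_partitions(net.nodes):
        assignment = {n: i for i, block in enumerate(partition) for n in block}
        best = max(best, modularity(net, assignment))
    return best


class TestModularityValue:
    def test_two_triangles_half(self, two_triangles):
        assignment = {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}
        assert modularity(two_triangles, assignment) == pytest.approx(0.5)

    def test_single_module_is_zero(self, two_triangles):
        assignment = {n: 1 for n in two_triangles}
        assert modularity(two_triangles, assignment) == pytest.approx(0.0)

    def test_k4_split_negative(self):
        g = nx.complete_graph(4)
        assignment = {0: 1, 1: 1, 2: 2, 3: 2}
        assert modularity(g, assignment) == pytest.approx(-1 / 6)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            g = random_graph(rng, n_max=8)
            assignment = {n: int(rng.integers(1, 4)) for n in g.nodes}
            assert modularity(g, assignment) == pytest.approx(
                brute_force_modularity(g, assignment), abs=1e-12
            )

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            modularity(g, {"a": 1})


class TestModuleDetection:
    def test_two_triangles_recovered_exactly(self, two_triangles):
        part = detect_modules(two_triangles)
        assert part.modularity_q == pytest.approx(0.5)
        assert {frozenset(part.members(m)) for m in (1, 2)} == {
            frozenset("abc"), frozenset("def")
        }
        # exhaustive search confirms 0.5 is the global optimum
        assert exhaustive_best_q(two_triangles) == pytest.approx(0.5)

    def test_single_edge(self):
        part = detect_modules(nx.Graph([("a", "b")]))
        assert part.n_modules == 1
        assert part.modularity_q == pytest.approx(0.0)

    def test_near_optimal_on_small_graphs(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            g = random_graph(rng, n_max=7)
            part = detect_modules(g)
            assert part.modularity_q >= exhaustive_best_q(g) - 0.05

    def test_stored_q_matches_recomputation(self, two_triangles, sim_default):
        part = detect_modules(two_triangles)
        assert modularity(two_triangles, part.assignment) == part.modularity_q

    def test_never_below_trivial_partitions(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = random_graph(rng, n_max=8)
            part = detect_modules(g)
            one = modularity(g, {n: 1 for n in g.nodes})
            singles = modularity(g, {n: i for i, n in enumerate(g.nodes)})
            assert part.modularity_q >= max(one, singles) - 1e-12

    def test_module_ids_sorted_by_size(self, two_triangles):
        two_triangles.add_edge("f", "g")  # second block now biggest
        part = detect_modules(two_triangles)
        sizes = [part.sizes[m] for m in sorted(part.sizes)]
        assert sizes == sorted(sizes, reverse=True)

    def test_major_module_threshold_strict(self, two_triangles):
        part = detect_modules(two_triangles, min_major_size=3)
        assert part.major_modules == []  # size 3 is not > 3
        part = detect_modules(two_triangles, min_major_size=2)
        assert part.major_modules == [1, 2]


class TestComposition:
    def _net_with_phyla(self, phyla_by_node):
        g = nx.Graph()
        nodes = list(phyla_by_node)
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b)
        for n, phylum in phyla_by_node.items():
            g.nodes[n]["phylum"] = phylum
        return g

    def test_fractions(self):
        g = self._net_with_phyla(
            {"a": "Proteobacteria", "b": "Proteobacteria",
             "c": "Proteobacteria", "d": "Firmicutes"}
        )
        part = detect_modules(g)
        assignment = {n: 1 for n in g.nodes}
        part.assignment = assignment
        comp = module_composition(g, part, rank="phylum")
        fractions = dict(zip(comp["taxon"], comp["fraction"]))
        assert fractions == {"Proteobacteria": 0.75, "Firmicutes": 0.25}

    def test_unknown_pooled_as_unclassified(self):
        g = self._net_with_phyla({"a": "unknown", "b": "unknown"})
        part = detect_modules(g)
        comp = module_composition(g, part, rank="phylum")
        assert list(comp["taxon"]) == ["unclassified"]
        assert comp["fraction"].iloc[0] == 1.0

    def test_fractions_sum_to_one_per_module(self, two_triangles):
        for n in two_triangles.nodes:
            two_triangles.nodes[n]["phylum"] = "P" + n
        part = detect_modules(two_triangles)
        comp = module_composition(two_triangles, part, rank="phylum")
        sums = comp.groupby("module")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_unknown_rank_rejected(self, two_triangles):
        part = detect_modules(two_triangles)
        with pytest.raises(ValueError, match="rank"):
            module_composition(two_triangles, part, rank="domain")
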