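import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coocnet.io import RANKS, OtuTable
from coocnet.simulate import SimulationConfig, simulate_otu_table


def make_table(counts: np.ndarray, groups=None, otu_ids=None, sample_ids=None,
               taxonomy=None) -> OtuTable:
    """Small OtuTable factory for hand-built fixtures."""
    n_samples, n_otus = counts.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n_samples)]
    otu_ids = otu_ids or [f"OTU{i}" for i in range(n_otus)]
    groups = groups or ["G1"] * n_samples
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            [["Bacteria"] + ["unknown"] * 6] * n_otus,
            index=otu_ids, columns=list(RANKS),
        )
    return OtuTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        taxonomy=taxonomy,
        groups=pd.Series(groups, index=sample_ids),
    )


@pytest.fixture(scope="session")
def sim_default():
    """One moderately sized simulated dataset shared across tests."""
    cfg = SimulationConfig(
        n_otus=400,
        samples_per_group=(70, 60, 70),
        sequencing_depth=30_000,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_otu_table(cfg)


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f")])
    return g


def random_graph(rng: np.random.Generator, n_max: int = 8,
                 connected: bool = False) -> nx.Graph:
    """Random labelled graph with >= 2 nodes and >= 1 edge."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.25, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        if g.number_of_edges() == 0:
            continue
        if connected and not nx.is_connected(g):
            continue
        return g
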