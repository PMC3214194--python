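import networkx as nx
import numpy as np
import pytest

from coexnet import random_weighted_network


def make_graph(edges, nodes=()):
    """Graph from (u, v, w) triples plus optional isolated nodes."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture
def path_abc():
    return make_graph([("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def triangle_plus_isolate():
    return make_graph(
        [("a", "b", 0.1), ("a", "c", 0.2), ("b", "c", 0.3)], nodes=["d"]
    )


@pytest.fixture
def barbell():
    """Two triangles joined by a single bridge edge."""
    return make_graph(
        [
            ("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0),
            ("x", "y", 1.0), ("x", "z", 1.0), ("y", "z", 1.0),
            ("c", "x", 1.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_networks(count, max_nodes, seed0=100, min_nodes=2, edge_prob=0.4):
    """Deterministic stream of small random weighted networks."""
    rng = np.random.default_rng(seed0)
    for k in range(count):
        n = int(rng.integers(min_nodes, max_nodes + 1))
        yield random_weighted_network(n, edge_prob, seed=seed0 + k)
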