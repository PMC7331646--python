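import networkx as nx
import numpy as np
import pytest

from braincurv import BrainNetwork


def make_network(weights, hemisphere=None) -> BrainNetwork:
    """BrainNetwork from a weight matrix with generated labels."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if hemisphere is None:
        hemisphere = ("left",) * n
    ids = tuple(f"n{i:02d}" for i in range(n))
    return BrainNetwork(ids, ids, tuple(hemisphere), w)


def complete_network(n: int, weight: float = 1.0) -> BrainNetwork:
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return make_network(w)


def path_network(n: int) -> BrainNetwork:
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return make_network(w)


def random_connected_network(
    rng: np.random.Generator, n_nodes: int, p: float = 0.5, max_weight: int = 10
) -> BrainNetwork:
    """Random connected graph with positive integer weights (oracle-exact)."""
    while True:
        graph = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(graph) and graph.number_of_edges() > 0:
            break
    w = np.zeros((n_nodes, n_nodes))
    for i, j in graph.edges:
        w[i, j] = w[j, i] = float(rng.integers(1, max_weight + 1))
    return make_network(w)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


@pytest.fixture
def k3() -> BrainNetwork:
    return complete_network(3)
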