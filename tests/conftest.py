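import networkx as nx
import numpy as np
import pytest

from missnet.graph_core import Graph


@pytest.fixture
def path3() -> Graph:
    """Path 0-1-2."""
    return Graph.from_edges([(0, 1), (1, 2)])


@pytest.fixture
def cycle4() -> Graph:
    """4-cycle 0-1-2-3-0."""
    return Graph.from_edges([(0, 1), (1, 2), (2, 3), (0, 3)])


@pytest.fixture
def star4() -> Graph:
    """Star with center 0 and 4 leaves."""
    return Graph.from_edges([(0, i) for i in range(1, 5)])


@pytest.fixture
def two_cliques() -> Graph:
    """Two disjoint K5 cliques: nodes 0-4 and 5-9."""
    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
    return Graph.from_edges(edges)


def random_connected_graph(n: int, m: int, seed: int) -> Graph:
    """Connected G(n, m)-style graph: a uniform spanning structure plus
    uniform extra edges."""
    if m < n - 1:
        raise ValueError("connected graph needs m >= n - 1")
    rng = np.random.default_rng(seed)
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    while not nx.is_connected(g) or g.number_of_nodes() != n:
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    return Graph.from_edges(g.edges(), nodes=range(n))


@pytest.fixture
def random_graph_factory():
    return random_connected_graph
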