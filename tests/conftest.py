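import networkx as nx
import numpy as np
import pytest

from molnet import WeightedGraph


def make_graph(edge_list, n=None, ids=None, build_method="complete"):
    """WeightedGraph from (u, v, similarity) triples; length = 1/similarity
    unless a 4th element gives it explicitly."""
    g = nx.Graph()
    nodes = set()
    for e in edge_list:
        u, v, w = e[0], e[1], e[2]
        length = e[3] if len(e) > 3 else 1.0 / w
        g.add_edge(u, v, weight=float(w), length=float(length))
        nodes.update((u, v))
    if n is None:
        n = max(nodes) + 1
    g.add_nodes_from(range(n))
    if ids is None:
        ids = [str(i) for i in range(n)]
    return WeightedGraph(ids=ids, graph=g, build_method=build_method)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_similarity():
    """Factory for random symmetric similarity matrices in (0, 1)."""

    def _make(n, seed=0):
        r = np.random.default_rng(seed)
        s = r.random((n, n))
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 0.0)
        return s

    return _make


@pytest.fixture(scope="session")
def planted_set():
    """Small planted-cluster synthetic set shared across tests."""
    from molnet import SyntheticSpec, generate_synthetic_molecules

    return generate_synthetic_molecules(
        SyntheticSpec(sizes=(40, 40, 40), seed=11))
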