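import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_graph
from molnet import (
    Partition,
    WeightedGraph,
    leading_eigenvector_partition,
    leiden_partition,
    modularity,
    tmfg_filter,
)


def two_cliques(k=5):
    """Two k-cliques joined by a single edge."""
    edges = []
    for base in (0, k):
        edges += [(base + i, base + j, 1.0, 1.0)
                  for i, j in itertools.combinations(range(k), 2)]
    edges.append((0, k, 1.0, 1.0))
    return make_graph(edges)


def uniform_complete(n):
    return make_graph([(i, j, 1.0, 1.0)
                       for i, j in itertools.combinations(range(n), 2)])


class TestPartition:
    def test_labels_relabelled_contiguously(self):
        p = Partition(ids=list("abcd"), labels=np.array([7, 7, 2, 9]))
        np.testing.assert_array_equal(p.labels, [0, 0, 1, 2])
        assert p.n_communities == 3
        assert p.sizes() == [2, 1, 1]

    def test_coverage_enforced(self):
        with pytest.raises(ValueError):
            Partition(ids=list("abc"), labels=np.array([0, 1]))


class TestModularity:
    def test_single_block_is_exactly_zero(self, random_similarity):
        g = tmfg_filter(random_similarity(12, seed=1))
        p = Partition(ids=list(g.ids), labels=np.zeros(12, dtype=int))
        assert modularity(g, p) == pytest.approx(0.0, abs=1e-14)

    def test_two_disjoint_triangles(self):
        g = make_graph([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                        (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)])
        p = Partition(ids=list(g.ids), labels=np.array([0, 0, 0, 1, 1, 1]))
        assert modularity(g, p) == pytest.approx(0.5, abs=1e-14)

    def test_singletons_closed_form(self, random_similarity):
        g = tmfg_filter(random_similarity(9, seed=2))
        p = Partition(ids=list(g.ids), labels=np.arange(9))
        k = g.similarity_matrix().sum(axis=1)
        expected = -float(np.sum((k / k.sum()) ** 2))
        assert modularity(g, p) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_networkx(self, random_similarity):
        g = tmfg_filter(random_similarity(20, seed=3))
        labels = np.random.default_rng(0).integers(0, 4, 20)
        p = Partition(ids=list(g.ids), labels=labels)
        communities = [set(np.flatnonzero(p.labels == c))
                       for c in range(p.n_communities)]
        ref = nx.community.modularity(g.graph, communities, weight="weight")
        assert modularity(g, p) == pytest.approx(ref, abs=1e-12)


class TestLeadingEigenvector:
    def test_uniform_complete_graph_indivisible(self):
        p = leading_eigenvector_partition(uniform_complete(8))
        assert p.n_communities == 1

    def test_two_cliques_split_at_modularity_optimum(self):
        g = two_cliques(5)
        p = leading_eigenvector_partition(g)
        assert p.n_communities == 2
        assert len(set(p.labels[:5])) == 1 and len(set(p.labels[5:])) == 1
        # returned Q equals the brute-force maximum over all 2-way splits
        q = modularity(g, p)
        best = max(
            modularity(g, Partition(ids=list(g.ids), labels=np.array(assign)))
            for assign in itertools.product([0, 1], repeat=10)
            if len(set(assign)) == 2
        )
        assert q == pytest.approx(best, abs=1e-12)

    def test_recovers_planted_clusters_on_similarity_graph(self):
        # complete similarity graph with three well-separated blocks
        rng = np.random.default_rng(1)
        lab = np.repeat([0, 1, 2], 30)
        s = np.where(lab[:, None] == lab[None, :], 0.9, 0.1)
        s = s + rng.random((90, 90)) * 0.05
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 0.0)
        g = nx.Graph()
        for i, j in itertools.combinations(range(90), 2):
            g.add_edge(i, j, weight=s[i, j], length=1.0 - s[i, j])
        wg = WeightedGraph(ids=[str(i) for i in range(90)], graph=g,
                           build_method="complete")
        p = leading_eigenvector_partition(wg)
        planted = Partition(ids=list(wg.ids), labels=lab)
        from molnet import adjusted_rand_index

        assert adjusted_rand_index(p, planted) >= 0.9

    def test_matches_igraph_reference_quality(self, random_similarity):
        # independent implementation of the same procedure: qualities agree
        import igraph as ig

        g = tmfg_filter(random_similarity(30, seed=5))
        ours = modularity(g, leading_eigenvector_partition(g))
        edges = list(g.graph.edges())
        weights = [g.graph.edges[e]["weight"] for e in edges]
        ref_part = ig.Graph(n=30, edges=edges).community_leading_eigenvector(
            weights=weights)
        ref = Partition(ids=list(g.ids), labels=np.array(ref_part.membership))
        assert ours == pytest.approx(modularity(g, ref), abs=0.05)

    def test_deterministic(self, random_similarity):
        g = tmfg_filter(random_similarity(25, seed=8))
        p1 = leading_eigenvector_partition(g)
        p2 = leading_eigenvector_partition(g)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_disconnected_rejected(self):
        g = make_graph([(0, 1, 1.0)], n=3)
        with pytest.raises(ValueError, match="connected"):
            leading_eigenvector_partition(g)


class TestLeiden:
    def test_two_cliques_resolution_one(self):
        p = leiden_partition(two_cliques(5), resolution=1.0, seed=0)
        assert p.n_communities == 2

    def test_seeded_determinism(self, random_similarity):
        g = tmfg_filter(random_similarity(40, seed=2))
        p1 = leiden_partition(g, seed=123)
        p2 = leiden_partition(g, seed=123)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_quality_at_least_leading_eigenvector(self, random_similarity):
        # paired comparison on 20 random planted graphs
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = 24
            lab = rng.integers(0, 3, n)
            s = np.where(lab[:, None] == lab[None, :], 0.7, 0.2)
            s = s + rng.random((n, n)) * 0.1
            s = 0.5 * (s + s.T)
            np.fill_diagonal(s, 0.0)
            g = tmfg_filter(s)
            q_le = modularity(g, leading_eigenvector_partition(g))
            q_ld = modularity(g, leiden_partition(g, seed=trial))
            assert q_ld >= q_le - 1e-12

    def test_communities_internally_connected(self, random_similarity):
        g = tmfg_filter(random_similarity(50, seed=7))
        p = leiden_partition(g, seed=3)
        for block in p.blocks():
            sub = g.graph.subgraph(block.tolist())
            assert nx.is_connected(sub)

    def test_positive_modularity_on_planted_structure(self, planted_set):
        from molnet import distance_to_similarity, hamming_matrix

        d = hamming_matrix(planted_set.fingerprints, ids=planted_set.ids)
        g = tmfg_filter(distance_to_similarity(d), distances=d)
        for part in (leiden_partition(g, seed=1),
                     leading_eigenvector_partition(g)):
            assert modularity(g, part) > 0.0

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            leiden_partition(two_cliques(4), resolution=0.0)
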