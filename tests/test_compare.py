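import itertools
import math

import numpy as np
import pytest

from molnet import (
    Partition,
    adjusted_rand_index,
    build_contingency,
    compare_partitions,
    normalized_mutual_information,
    rand_index,
    split_join_distance,
    variation_of_information,
)


def part(labels, ids=None):
    labels = np.asarray(labels)
    if ids is None:
        ids = [str(i) for i in range(len(labels))]
    return Partition(ids=ids, labels=labels)


def random_pair(rng, n=None):
    n = n or int(rng.integers(2, 13))
    return (part(rng.integers(0, rng.integers(1, 5) + 1, n)),
            part(rng.integers(0, rng.integers(1, 5) + 1, n)))


class TestContingency:
    def test_identical_partitions_give_diagonal(self):
        p = part([0, 0, 1, 1, 2])
        t = build_contingency(p, p)
        np.testing.assert_array_equal(t.counts, np.diag([2, 2, 1]))

    def test_hand_intersection(self):
        t = build_contingency(part([0, 0, 1, 1]), part([0, 0, 0, 1]))
        np.testing.assert_array_equal(t.counts, [[2, 0], [1, 1]])

    def test_marginals_are_block_sizes(self, rng):
        for _ in range(20):
            p1, p2 = random_pair(rng)
            t = build_contingency(p1, p2)
            assert t.n == p1.n
            np.testing.assert_array_equal(t.row_sums, np.bincount(p1.labels))
            np.testing.assert_array_equal(t.col_sums, np.bincount(p2.labels))

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different node sets"):
            build_contingency(part([0, 1], ids=["a", "b"]),
                              part([0, 1], ids=["a", "c"]))


class TestVoi:
    def test_identical_partitions_zero(self):
        p = part([0, 1, 0, 2, 1])
        assert variation_of_information(p, p) == 0.0

    def test_single_block_vs_even_split(self):
        assert variation_of_information(
            part([0, 0, 0, 0]), part([0, 0, 1, 1])) == pytest.approx(math.log(2))

    def test_symmetry(self, rng):
        for _ in range(30):
            p1, p2 = random_pair(rng)
            assert variation_of_information(p1, p2) == pytest.approx(
                variation_of_information(p2, p1), abs=1e-12)


class TestNmi:
    def test_identical_nontrivial_is_one(self):
        p = part([0, 0, 1, 1, 2])
        assert normalized_mutual_information(p, p) == pytest.approx(1.0)

    def test_single_block_vs_anything_is_zero(self):
        # the single-community case forces NMI = 0 regardless of the other side
        single = part([0] * 6)
        other = part([0, 1, 2, 0, 1, 2])
        assert normalized_mutual_information(single, other) == 0.0

    def test_both_single_block_convention(self):
        assert normalized_mutual_information(part([0, 0, 0]), part([0, 0, 0])) == 1.0

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [normalized_mutual_information(part(rng.integers(0, 4, 1000)),
                                              part(rng.integers(0, 4, 1000)))
                for _ in range(100)]
        assert max(vals) < 0.05


class TestSjd:
    def test_identical_zero(self):
        p = part([0, 1, 1, 2])
        assert split_join_distance(p, p) == 0

    def test_single_block_vs_even_split(self):
        assert split_join_distance(part([0, 0, 0, 0]), part([0, 0, 1, 1])) == 2

    def test_single_block_vs_singletons_closed_form(self):
        for n in (3, 7, 11):
            assert split_join_distance(part([0] * n), part(range(n))) == n - 1


class TestRi:
    def test_identical_is_one(self):
        p = part([0, 1, 0, 2])
        assert rand_index(p, p) == 1.0

    def test_hand_enumeration(self):
        # {ab|cd} vs {abc|d}: c1 = 1 (ab), c2 = 2 (ad, bd) of 6 pairs
        assert rand_index(part([0, 0, 1, 1]), part([0, 0, 0, 1])) == 0.5

    def test_matches_pair_loop_oracle(self, rng):
        for _ in range(40):
            p1, p2 = random_pair(rng)
            agree = 0
            for i, j in itertools.combinations(range(p1.n), 2):
                same1 = p1.labels[i] == p1.labels[j]
                same2 = p2.labels[i] == p2.labels[j]
                agree += same1 == same2
            expected = agree / math.comb(p1.n, 2)
            assert rand_index(p1, p2) == pytest.approx(expected, abs=1e-12)


class TestAri:
    def test_identical_is_one(self):
        p = part([0, 1, 0, 2, 2])
        assert adjusted_rand_index(p, p) == 1.0

    def test_single_block_vs_anything_is_zero(self):
        assert adjusted_rand_index(part([0] * 6), part([0, 1, 2, 0, 1, 2])) == 0.0

    def test_hand_evaluation(self):
        # index = 1, expected = 1, max = 2.5 -> ARI = 0
        assert adjusted_rand_index(part([0, 0, 1, 1]),
                                   part([0, 0, 0, 1])) == pytest.approx(0.0)

    def test_degenerate_pair_guarded(self):
        # the degenerate denominator only arises for identical partitions:
        # all-singletons (label permutations included) or both single-block
        singletons = part([0, 1, 2])
        with pytest.warns(UserWarning, match="degenerate"):
            assert adjusted_rand_index(singletons, part([2, 0, 1])) == 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert adjusted_rand_index(part([0, 0, 0]), part([0, 0, 0])) == 1.0

    def test_permutation_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 5, 200)
        p1 = part(labels)
        vals = [adjusted_rand_index(p1, part(rng.permutation(labels)))
                for _ in range(500)]
        assert abs(np.mean(vals)) < 0.02


class TestCrossMetricIdentities:
    def test_all_metrics_agree_on_identity(self, rng):
        for _ in range(50):
            p1, p2 = random_pair(rng)
            identical = np.array_equal(p1.labels, p2.labels)
            r = compare_partitions(p1, p2)
            assert (r.voi == 0.0) == identical
            assert (r.nmi == pytest.approx(1.0)) == identical
            assert (r.sjd == 0) == identical
            assert (r.ri == 1.0) == identical
            assert (r.ari == pytest.approx(1.0)) == identical

    def test_agrees_with_igraph_and_sklearn_oracles(self, rng):
        import igraph
        from sklearn.metrics import (adjusted_rand_score,
                                     normalized_mutual_info_score)

        for _ in range(100):
            p1, p2 = random_pair(rng)
            r = compare_partitions(p1, p2)
            m1, m2 = list(p1.labels), list(p2.labels)
            assert r.voi == pytest.approx(
                igraph.compare_communities(m1, m2, method="vi"), abs=1e-12)
            assert r.sjd == igraph.compare_communities(m1, m2, method="split-join")
            assert r.ari == pytest.approx(adjusted_rand_score(m1, m2), abs=1e-12)
            if p1.n_communities > 1 or p2.n_communities > 1:
                assert r.nmi == pytest.approx(
                    normalized_mutual_info_score(m1, m2,
                                                 average_method="arithmetic"),
                    abs=1e-12)
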