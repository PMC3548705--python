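"""k-means engine: seeding, assignment, objective, convergence."""

import numpy as np
import pytest

from seco import kmeans


def brute_force_min_wss(X, k):
    """Exhaustive minimum wss over all partitions into k nonempty blocks,
    enumerated via restricted growth strings."""
    n = X.shape[0]
    best = np.inf

    def rec(i, labels, n_used):
        nonlocal best
        if n - i < k - n_used:
            return
        if i == n:
            if n_used != k:
                return
            w = 0.0
            lab = np.array(labels)
            for c in range(k):
                block = X[lab == c]
                w += ((block - block.mean(axis=0)) ** 2).sum()
            best = min(best, w)
            return
        for c in range(n_used):
            labels.append(c)
            rec(i + 1, labels, n_used)
            labels.pop()
        if n_used < k:
            labels.append(n_used)
            rec(i + 1, labels, n_used + 1)
            labels.pop()

    rec(0, [], 0)
    return best


class TestSeeding:
    def test_k_equals_n_returns_all_rows(self):
        X = np.arange(12.0).reshape(6, 2)
        P = kmeans.seed_prototypes(X, 6, np.random.default_rng(0))
        assert sorted(map(tuple, P)) == sorted(map(tuple, X))

    def test_k_one_returns_a_data_row(self):
        X = np.arange(10.0).reshape(5, 2)
        P = kmeans.seed_prototypes(X, 1, np.random.default_rng(3))
        assert any(np.array_equal(P[0], row) for row in X)

    def test_same_seed_same_prototypes(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        P1 = kmeans.seed_prototypes(X, 5, np.random.default_rng(42))
        P2 = kmeans.seed_prototypes(X, 5, np.random.default_rng(42))
        np.testing.assert_array_equal(P1, P2)

    def test_k_greater_than_n_errors_naming_both(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="k=5.*n=3"):
            kmeans.seed_prototypes(X, 5, np.random.default_rng(0))


class TestAssignment:
    def test_data_equal_prototypes(self):
        X = np.array([[0.0, 0], [3, 0], [0, 3]])
        np.testing.assert_array_equal(
            kmeans.assign_labels(X, X), [0, 1, 2]
        )

    def test_equidistant_tie_goes_to_lower_index(self):
        # point at 5 is equidistant to prototypes 4 and 6
        labels = kmeans.assign_labels([[5.0]], [[0.0], [4.0], [6.0]])
        assert labels[0] == 1

    def test_one_dimensional_example(self):
        labels = kmeans.assign_labels([[0.0], [10.0]], [[1.0], [9.0]])
        np.testing.assert_array_equal(labels, [0, 1])


class TestWithinSSQ:
    def test_zero_when_points_equal_prototypes(self):
        X = np.array([[1.0, 2], [3, 4]])
        assert kmeans.within_ssq(X, [0, 1], X) == 0.0

    def test_single_cluster_at_mean_gives_total_ssq(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        wss = kmeans.within_ssq(X, np.zeros(20, dtype=int), X.mean(0)[None])
        assert wss == pytest.approx(kmeans.total_ssq(X), rel=1e-12)

    def test_hand_computation(self):
        assert kmeans.within_ssq([[0.0], [2.0]], [0, 0], [[1.0]]) == 2.0

    def test_empty_cluster_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            kmeans.within_ssq([[0.0], [1.0]], [0, 0], [[0.0], [5.0]])


class TestFit:
    def test_k_distinct_points_gives_zero_wss(self):
        X = np.array([[0.0, 0], [5, 0], [0, 5]])
        sol = kmeans.fit_kmeans(X, 3, seed=0)
        assert sol.wss == 0.0
        assert sorted(np.bincount(sol.labels)) == [1, 1, 1]

    def test_two_blob_global_optimum(self, two_blobs):
        sol = kmeans.fit_kmeans(two_blobs, 2, seed=1)
        assert sol.wss == pytest.approx(0.01, rel=1e-9)
        assert sol.wss == pytest.approx(
            brute_force_min_wss(two_blobs, 2), rel=1e-9
        )
        np.testing.assert_allclose(
            sorted(sol.prototypes.ravel()), [0.05, 10.05]
        )

    def test_wss_plus_delta_is_total(self):
        X = np.random.default_rng(2).normal(size=(100, 3))
        for k in (2, 5):
            sol = kmeans.fit_kmeans(X, k, seed=3)
            assert sol.wss + sol.delta_ssq == pytest.approx(
                kmeans.total_ssq(X), rel=1e-9
            )

    def test_batch_and_online_wss_monotone(self):
        X = np.random.default_rng(4).normal(size=(200, 3))
        sol = kmeans.fit_kmeans(X, 4, seed=9, collect_history=True)
        batch = sol.history["batch"]
        online = sol.history["online"]
        assert all(b >= a - 1e-9 for a, b in zip(batch[1:], batch))
        seq = [batch[-1]] + online
        assert all(b >= a - 1e-9 for a, b in zip(seq[1:], seq))
        assert sol.wss <= batch[0] + 1e-9

    def test_best_of_seeds_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 2))
        expected = brute_force_min_wss(X, 3)
        best = min(kmeans.fit_kmeans(X, 3, seed=s).wss for s in range(200))
        assert best == pytest.approx(expected, rel=1e-9)

    def test_row_permutation_with_same_initial_prototypes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2)) + np.repeat(
            np.array([[0, 0], [6, 6], [0, 6]]), 20, axis=0
        )
        P0 = kmeans.seed_prototypes(X, 3, np.random.default_rng(1))
        perm = rng.permutation(60)
        a = kmeans.fit_from_prototypes(X, P0)
        b = kmeans.fit_from_prototypes(X[perm], P0)
        assert a.wss == pytest.approx(b.wss, rel=1e-9)

    def test_empty_cluster_reseeded_not_raised(self, two_blobs):
        # both prototypes start on the left blob; cluster 1 is emptied and
        # must be re-seeded at the farthest point
        sol = kmeans.fit_from_prototypes(two_blobs, [[0.0], [0.0]])
        assert sorted(np.bincount(sol.labels, minlength=2)) == [2, 2]
        assert sol.wss == pytest.approx(0.01, rel=1e-9)

    def test_unreachable_k_errors(self):
        with pytest.raises(ValueError):
            kmeans.fit_kmeans(np.zeros((3, 1)), 4, seed=0)

    def test_solution_json_roundtrip(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        sol = kmeans.fit_kmeans(X, 3, seed=7)
        back = kmeans.ClusterSolution.from_json(sol.to_json())
        np.testing.assert_array_equal(back.labels, sol.labels)
        np.testing.assert_allclose(back.prototypes, sol.prototypes)
        assert back.wss == sol.wss and back.seed == 7


def test_every_cluster_populated_on_overlapping_data():
    X = np.random.default_rng(3).normal(size=(300, 3))
    for seed in range(5):
        sol = kmeans.fit_kmeans(X, 8, seed=seed)
        assert (np.bincount(sol.labels, minlength=8) > 0).all()


def test_invalid_data_rejected():
    with pytest.raises(ValueError, match="finite"):
        kmeans.as_data_matrix([[np.nan, 1.0]])
    with pytest.raises(ValueError):
        kmeans.as_data_matrix(np.zeros((0, 3)))
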