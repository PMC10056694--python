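"""Tests for affinity construction, spectral module identification,
cluster matching, ARI and network-distance utilities."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bzinbnet.correlation import CorrMatrix, corr_matrix
from bzinbnet.modules import (
    AffinityMatrix,
    adjusted_rand_index,
    eigengap_k,
    match_clusters,
    nested_distance_curve,
    spectral_cluster,
    standardize_counts,
    submatrix_distance,
    to_affinity,
)
from bzinbnet.pipeline import module_recovery_experiment
from bzinbnet.simulate import (
    ClusterCraftConfig,
    craft_cluster_signal,
    generate_baseline_matrix,
)


def block_affinity(sizes, within=1.0, between=0.0, noise=0.0, seed=0):
    n = sum(sizes)
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    a = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        rng = np.random.default_rng(seed)
        sym = rng.normal(0, noise, (n, n))
        a += (sym + sym.T) / 2
        a = np.clip(a, 0, None)
    np.fill_diagonal(a, 0.0)
    return a, labels


class TestAffinity:
    def test_clamps_negatives_and_diagonal(self):
        vals = pd.DataFrame(
            [[1.0, -0.4, 0.2], [-0.4, 1.0, 0.5], [0.2, 0.5, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        aff = to_affinity(CorrMatrix(vals, "spearman", vals * 0))
        assert aff.values[0, 1] == 0.0
        assert np.all(np.diag(aff.values) == 0.0)
        assert aff.values[0, 2] == pytest.approx(0.2)

    def test_missing_entries_warn_and_zero(self):
        vals = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.warns(UserWarning):
            aff = to_affinity(vals)
        assert aff.values[0, 1] == 0.0

    def test_symmetrizes_by_averaging(self):
        vals = np.array([[1.0, 0.2], [0.4, 1.0]])
        aff = to_affinity(vals)
        assert aff.values[0, 1] == pytest.approx(0.3)
        assert aff.values[1, 0] == pytest.approx(0.3)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            to_affinity(np.ones((2, 3)))


class TestSpectral:
    def test_two_perfect_blocks(self):
        a, truth = block_affinity([5, 7])
        sol = spectral_cluster(a, k=2, seed=0)
        assert adjusted_rand_index(sol.labels, truth) == 1.0
        assert set(sol.labels) == {1, 2}

    def test_uninformative_affinity_is_valid(self):
        a = np.ones((8, 8)) - np.eye(8)
        sol = spectral_cluster(a, k=2, seed=0)
        assert sol.labels.shape == (8,)
        assert set(sol.labels) <= {1, 2}

    def test_zero_degree_node_assigned_and_flagged(self):
        a, _ = block_affinity([4, 4])
        a[3, :] = a[:, 3] = 0.0  # isolate node 3
        sol = spectral_cluster(a, k=2, seed=0)
        assert 3 in sol.isolated
        assert sol.labels[3] in (1, 2)

    def test_noisy_blocks_recovered(self):
        a, truth = block_affinity([10, 10, 10], within=0.6, noise=0.1, seed=1)
        sol = spectral_cluster(a, k=3, seed=1)
        assert adjusted_rand_index(sol.labels, truth) == 1.0

    def test_permutation_equivariance(self):
        a, truth = block_affinity([6, 6, 6], within=0.7, noise=0.05, seed=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(18)
        sol = spectral_cluster(a, k=3, seed=4)
        sol_p = spectral_cluster(a[np.ix_(perm, perm)], k=3, seed=4)
        assert adjusted_rand_index(sol_p.labels, truth[perm]) == pytest.approx(
            adjusted_rand_index(sol.labels, truth)
        )


class TestEigengap:
    @pytest.mark.parametrize("sizes,expected", [([6, 6], 2), ([5, 5, 5], 3)])
    def test_perfect_blocks(self, sizes, expected):
        a, _ = block_affinity(sizes)
        assert eigengap_k(a, kmax=6) == expected

    def test_kmax_validation(self):
        a, _ = block_affinity([3, 3])
        with pytest.raises(ValueError):
            eigengap_k(a, kmax=6)


def brute_force_with_step1(pred, truth, k):
    """Oracle: best bijection restricted to honoring the mutual-mode
    matches of step 1."""
    c = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        c[t - 1, p - 1] += 1
    mode_pred = c.argmax(axis=1)
    mode_truth = c.argmax(axis=0)
    fixed = {}
    for t in range(k):
        p = mode_pred[t]
        if mode_truth[p] == t:
            fixed[p] = t
    rest_t = [t for t in range(k) if t not in set(fixed.values())]
    rest_p = [p for p in range(k) if p not in fixed]
    best = -1
    for perm in permutations(rest_t):
        score = sum(c[t, p] for p, t in fixed.items())
        score += sum(c[t, p] for t, p in zip(perm, rest_p))
        best = max(best, score)
    return best / len(pred)


class TestMatchClusters:
    def test_identity(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        res = match_clusters(labels, labels, k=3)
        assert res.accuracy == 1.0
        assert res.mapping == {1: 1, 2: 2, 3: 3}
        assert all(v == 1.0 for v in res.per_cluster.values())

    def test_label_swap_invariance(self):
        truth = np.array([1, 1, 2, 2, 3, 3])
        pred = np.array([2, 2, 1, 1, 3, 3])
        res = match_clusters(pred, truth, k=3)
        assert res.accuracy == 1.0
        assert res.mapping == {2: 1, 1: 2, 3: 3}

    def test_printed_confusion_example(self):
        """Three clusters of four with one misplaced element: accuracy
        11/12, equal to the brute-force maximum over all 3! bijections."""
        truth = np.repeat([1, 2, 3], 4)
        pred = truth.copy()
        pred[0] = 2  # one element of truth-cluster 1 predicted as 2
        res = match_clusters(pred, truth, k=3)
        assert res.accuracy == pytest.approx(11 / 12)
        best = max(
            sum(np.sum((truth == t) & (pred == p)) for t, p in zip((1, 2, 3), perm))
            for perm in permutations((1, 2, 3))
        )
        assert res.accuracy == pytest.approx(best / 12)

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_equals_restricted_brute_force(self, k):
        rng = np.random.default_rng(k)
        for _ in range(15):
            n = rng.integers(3 * k, 8 * k)
            truth = rng.integers(1, k + 1, n)
            pred = rng.integers(1, k + 1, n)
            # ensure all labels appear
            truth[: k] = np.arange(1, k + 1)
            pred[: k] = rng.permutation(np.arange(1, k + 1))
            res = match_clusters(pred, truth, k=k)
            assert res.accuracy == pytest.approx(
                brute_force_with_step1(pred, truth, k)
            )

    def test_large_k_falls_back_to_assignment(self):
        rng = np.random.default_rng(0)
        k = 12
        truth = np.tile(np.arange(1, k + 1), 6)
        pred = rng.integers(1, k + 1, truth.size)
        res = match_clusters(pred, truth, k=k, exhaustive_limit=3)
        assert set(res.mapping.keys()) == set(range(1, k + 1))
        assert sorted(res.mapping.values()) == list(range(1, k + 1))


class TestARI:
    def test_identical(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 1000)
        b = rng.integers(0, 5, 1000)
        assert abs(adjusted_rand_index(a, b)) < 0.05

    def test_hand_computed_contingency(self):
        # contingency [[2,1],[1,2]]: sum comb2(cells)=2, rows=cols=6, n=6
        a = [1, 1, 1, 2, 2, 2]
        b = [1, 1, 2, 1, 2, 2]
        expected = (2 - 6 * 6 / 15) / ((6 + 6) / 2 - 6 * 6 / 15)
        assert adjusted_rand_index(a, b) == pytest.approx(expected)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(10, 200)
            a = rng.integers(0, 6, n)
            b = rng.integers(0, 4, n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestDistances:
    def _pair(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        b = a.copy()
        return a, b

    def test_identical_matrices(self):
        a, b = self._pair()
        assert submatrix_distance(a, b) == 0.0

    def test_single_symmetric_difference(self):
        a, b = self._pair(1)
        b[1, 2] += 0.25
        b[2, 1] += 0.25
        assert submatrix_distance(a, b) == pytest.approx(np.sqrt(2) * 0.25)

    def test_elementwise_oracle_on_subset(self):
        rng = np.random.default_rng(3)
        a = rng.random((5, 5))
        b = rng.random((5, 5))
        ids = list("abcde")
        da = pd.DataFrame(a, index=ids, columns=ids)
        db = pd.DataFrame(b, index=ids, columns=ids)
        sub = ["b", "d", "e"]
        ii = [1, 3, 4]
        direct = np.sqrt(
            sum((a[i, j] - b[i, j]) ** 2 for i in ii for j in ii)
        )
        assert submatrix_distance(da, db, sub) == pytest.approx(direct)

    def test_unknown_features_rejected(self):
        a, b = self._pair(4)
        with pytest.raises(KeyError):
            submatrix_distance(a, b, features=[99])

    def test_nested_curve_properties(self):
        rng = np.random.default_rng(5)
        n = 12
        a = rng.random((n, n))
        a = (a + a.T) / 2
        b = a.copy()
        labels = np.repeat([1, 2, 3], 4)
        # perturb only cluster 2
        idx = np.flatnonzero(labels == 2)
        b[np.ix_(idx, idx)] += 0.5
        from bzinbnet.modules import ClusterSolution

        sol = ClusterSolution(labels, 3, 0, np.array([]))
        curve = nested_distance_curve(a, b, sol)
        sizes = [s for s, _ in curve]
        dists = [d for _, d in curve]
        assert sizes == [4, 8, 12]
        assert all(np.diff(dists) >= -1e-12)  # non-decreasing under nesting
        # the perturbed cluster is ranked first
        first_set_dist = dists[0]
        assert first_set_dist == pytest.approx(
            np.linalg.norm((a - b)[np.ix_(idx, idx)])
        )
        # identical matrices give an all-zero curve
        zero_curve = nested_distance_curve(a, a, sol)
        assert all(d == 0 for _, d in zero_curve)


class TestStandardize:
    def test_median_zero_and_constant_flagged(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4, 100], [5, 5, 5, 5, 5]], index=["f1", "f2"]
        )
        out, flags = standardize_counts(m)
        assert np.median(out.loc["f1"]) == pytest.approx(0.0)
        assert (out.loc["f2"] == 0).all()
        assert bool(flags["f2"]) and not bool(flags["f1"])

    def test_outlier_clipped_to_fence(self):
        row = np.array([1.0, 2, 3, 4, 5, 6, 7, 1000])
        m = pd.DataFrame([row], index=["f"])
        q1, q3 = np.percentile(row, [25, 75])
        fence = q3 + 3 * (q3 - q1)
        clipped = np.clip(row, q1 - 3 * (q3 - q1), fence)
        expected_max = (fence - np.median(clipped)) / clipped.std(ddof=1)
        out, _ = standardize_counts(m)
        assert out.loc["f"].max() == pytest.approx(expected_max)


class TestEndToEnd:
    def test_strong_signal_module_recovery(self):
        """Crafted clusters at weight 0.5 are sharply recovered from the
        complete-pairs Pearson affinity (strong-signal integration
        check of the generate -> craft -> affinity -> cluster chain)."""
        base = generate_baseline_matrix(80, 180, seed=0, mean_count=450.0)
        crafted, truth = craft_cluster_signal(
            base, ClusterCraftConfig(k=10, cluster_size=8, weight=0.5, seed=0)
        )
        cm = corr_matrix(crafted, method="pearson", complete_pairs_only=True)
        sol = spectral_cluster(to_affinity(cm), k=10, seed=0)
        assert adjusted_rand_index(sol.labels, truth) > 0.8

    def test_experiment_wrapper_smoke(self):
        res = module_recovery_experiment(
            method="pearson", n_features=30, n_samples=120,
            mean_count=200.0, k=3, cluster_size=10, weight=0.5, seed=1,
            fit_kwargs=dict(complete_pairs_only=True),
        )
        assert res.labels.shape == (30,)
        assert np.isfinite(res.ari) and np.isfinite(res.accuracy)
        assert res.ari > 0.3  # strong signal on the complete pairs
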