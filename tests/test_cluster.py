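import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_samples

import metaboratio as mr
from metaboratio.cluster import euclidean_kmeans, standardize_rows


class TestPearsonDistance:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert mr.pearson_distance(X)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_centered_negation_is_two(self):
        x = np.array([1.0, 2.0, 3.0])
        X = np.vstack([x, 2 * x.mean() - x])
        assert mr.pearson_distance(X)[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_value(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]])
        r = stats.pearsonr([1, 2, 3], [1, 2, 4]).statistic
        d = mr.pearson_distance(X)[0, 1]
        assert d == pytest.approx(1 - r, abs=1e-12)
        assert d == pytest.approx(0.01802, abs=1e-5)

    def test_zero_variance_row_errors(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            mr.pearson_distance(X)

    @pytest.mark.parametrize("seed", range(5))
    def test_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 10))
        a = rng.uniform(0.1, 5.0, size=(6, 1))
        b = rng.standard_normal((6, 1))
        np.testing.assert_allclose(
            mr.pearson_distance(a * X + b), mr.pearson_distance(X), atol=1e-12
        )


class TestKmeansCorrelation:
    def test_duplicated_rows_recover_partition(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        X = np.vstack([a] * 4 + [b] * 4) + rng.normal(0, 1e-6, (8, 8))
        labels = mr.kmeans_correlation(X, 2, seed=1)
        assert adjusted_rand_score([0, 0, 0, 0, 1, 1, 1, 1], labels) == 1.0

    def test_k_one_single_label(self):
        X = np.random.default_rng(0).standard_normal((5, 4))
        assert set(mr.kmeans_correlation(X, 1, seed=0)) == {0}

    def test_k_equals_n_zero_dispersion(self):
        X = np.random.default_rng(1).standard_normal((6, 5))
        labels = mr.kmeans_correlation(X, 6, seed=0)
        assert len(set(labels)) == 6
        assert mr.within_dispersion(standardize_rows(X), labels) == pytest.approx(0.0)

    def test_k_above_n_errors(self):
        X = np.random.default_rng(2).standard_normal((4, 5))
        with pytest.raises(ValueError, match="exceeds"):
            mr.kmeans_correlation(X, 5)

    def test_wss_non_increasing_over_k(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 6))
        Xs = standardize_rows(X)
        wss = []
        for k in range(1, 8):
            best = min(
                mr.within_dispersion(Xs, mr.kmeans_correlation(X, k, seed=s))
                for s in range(8)
            )
            wss.append(best)
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))


class TestConsensusCluster:
    def _blobs(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        c1 = rng.normal(0, 0.05, (n, 6)) + np.array([3, 1, -2, 0.5, 2, -1])
        c2 = rng.normal(0, 0.05, (n, 6)) + np.array([-1, 2, 3, -2, 0, 1])
        return np.vstack([c1, c2])

    def test_single_rep_matches_single_run(self):
        X = self._blobs()
        res = mr.consensus_cluster(X, 2, n_reps=1, seed=5)
        single = mr.kmeans_correlation(X, 2, seed=5)
        assert adjusted_rand_score(single, res.labels) == 1.0

    def test_separated_blobs_give_binary_coassociation(self):
        X = self._blobs()
        res = mr.consensus_cluster(X, 2, n_reps=40, seed=0)
        C = res.coassociation.to_numpy()
        assert np.isin(C, (0.0, 1.0)).all()
        assert (np.diag(C) == 1.0).all()
        assert adjusted_rand_score([0] * 12 + [1] * 12, res.labels) == 1.0

    def test_invalid_n_reps_errors(self):
        with pytest.raises(ValueError, match="n_reps"):
            mr.consensus_cluster(self._blobs(), 2, n_reps=0)

    def test_sample_permutation_invariance(self, ratio_panel):
        *_, scaled = ratio_panel
        res = mr.consensus_cluster(scaled, 5, n_reps=60, seed=2)
        perm = list(np.random.default_rng(0).permutation(scaled.data.index))
        res_p = mr.consensus_cluster(scaled.data.loc[perm], 5, n_reps=60, seed=2)
        aligned = res_p.labels.loc[res.labels.index]
        assert adjusted_rand_score(res.labels, aligned) == 1.0


class TestGapStatistic:
    def test_one_blob_selects_one(self):
        hits = sum(
            mr.gap_statistic(
                np.random.default_rng(s).standard_normal((60, 2)), range(1, 7), B=30, seed=s
            ).chosen_k
            == 1
            for s in range(5)
        )
        assert hits >= 4

    def test_two_distant_blobs_select_two(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(s)
            X = np.vstack(
                [rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + [10, 0]]
            )
            hits += mr.gap_statistic(X, range(1, 7), B=30, seed=s).chosen_k == 2
        assert hits >= 4

    def test_empty_k_range_errors(self):
        with pytest.raises(ValueError, match="k_range"):
            mr.gap_statistic(np.zeros((10, 2)), [])

    def test_single_point_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            mr.gap_statistic(np.zeros((1, 2)), [1, 2])


class TestElbow:
    def test_hand_pick(self):
        assert mr.elbow_k({1: 100.0, 2: 20.0, 3: 18.0, 4: 17.0}) == 2

    def test_linear_curve_ties_to_smallest(self):
        assert mr.elbow_k({1: 40.0, 2: 30.0, 3: 20.0, 4: 10.0}) == 1

    def test_two_points_errors(self):
        with pytest.raises(ValueError, match="3 points"):
            mr.elbow_k({1: 10.0, 2: 5.0})


class TestSilhouette:
    def test_hand_value(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        s, mean = mr.silhouette_widths(X, [0, 0, 1, 1], metric="euclidean")
        assert s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-9)
        assert mean == pytest.approx(s.mean())

    def test_equidistant_point_is_zero(self):
        # middle point has a == b, hence s = 0
        X = np.array([[0.0], [2.0], [4.0]])
        s, _ = mr.silhouette_widths(X, [0, 0, 1], metric="euclidean")
        assert s[1] == 0.0

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        s, _ = mr.silhouette_widths(X, [0, 0, 1], metric="euclidean")
        assert s[2] == 0.0

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="2 clusters"):
            mr.silhouette_widths(np.zeros((3, 2)), [0, 0, 0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((25, 4))
        labels = rng.integers(0, 4, 25)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 4
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        s, _ = mr.silhouette_widths(D, labels, metric="precomputed")
        # O(n^2) brute-force oracle
        for i in range(len(X)):
            own = labels == labels[i]
            if own.sum() == 1:
                assert s[i] == 0.0
                continue
            a = D[i, own].sum() / (own.sum() - 1)
            b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
            expected = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
            assert s[i] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        labels = rng.integers(0, 3, 30)
        s, _ = mr.silhouette_widths(X, labels, metric="euclidean")
        np.testing.assert_allclose(s, silhouette_samples(X, labels), atol=1e-6)


class TestSelectK:
    @pytest.mark.parametrize(
        "votes,expected",
        [((5, 5, 4), 5), ((1, 1, 1), 1), ((3, 4, 5), 5), ((4, 6, 6), 6), ((2, 7, 2), 2)],
    )
    def test_majority_with_silhouette_tiebreak(self, votes, expected):
        assert mr.select_k(*votes) == expected


class TestKDiagnostics:
    def test_recovers_planted_k_on_default_panel(self, ratio_panel):
        *_, scaled = ratio_panel
        diag = mr.k_diagnostics(scaled, seed=0)
        assert diag.combined_k == 5
        assert diag.silhouette_k == 5
        assert 1 in diag.wss and 1 in diag.gap  # gap/elbow curves probe k=1
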