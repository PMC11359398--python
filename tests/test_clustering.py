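import itertools

import numpy as np
import pytest

from histotex import (
    DegenerateInputError,
    FeatureTable,
    elbow_select,
    gmm_fit,
    kmeans_fit,
    predict_labels,
    standardize,
)
from histotex.clustering import select_knee


def table(X):
    X = np.asarray(X, dtype=float)
    ids = np.column_stack([np.arange(len(X)), np.zeros(len(X), dtype=int)])
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    return FeatureTable(ids=ids, X=X, column_names=names)


def brute_force_two_partition_wcss(X):
    """Oracle: exhaustive scan of all 2-partitions of the points."""
    n = len(X)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0.0
        for side in (mask, ~mask):
            if side.any():
                c = X[side].mean(axis=0)
                cost += ((X[side] - c) ** 2).sum()
        best = min(best, cost)
    return best


class TestStandardize:
    def test_two_point_column(self):
        ft = standardize(table([[1.0], [3.0]]))
        assert np.allclose(ft.X, [[-1.0], [1.0]])

    def test_constant_column_maps_to_zero(self):
        ft = standardize(table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(ft.X[:, 0] == 0.0)
        assert ft.X[:, 1].std() == pytest.approx(1.0)

    def test_idempotent(self, rng):
        ft = standardize(table(rng.standard_normal((20, 4))))
        again = standardize(ft)
        assert np.allclose(again.X, ft.X, atol=1e-9)

    def test_population_sd_and_stored_params(self, rng):
        X = rng.standard_normal((15, 3)) * 4 + 7
        ft = standardize(table(X))
        mean, sd = ft.standardization
        assert np.allclose(mean, X.mean(axis=0))
        assert np.allclose(sd, X.std(axis=0))  # population, not sample
        assert np.allclose(ft.X * sd + mean, X)

    def test_single_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize(table([[1.0, 2.0]]))


class TestKMeans:
    def test_k_equals_n_zero_wcss(self, rng):
        X = rng.standard_normal((6, 2))
        m = kmeans_fit(X, 6, seed=0)
        assert m.wcss == pytest.approx(0.0, abs=1e-12)

    def test_two_far_pairs_hand_geometry(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [100.0, 0.0], [100.0, 1.0]])
        m = kmeans_fit(X, 2, seed=1, n_init=5)
        assert m.wcss == pytest.approx(1.0)
        cents = sorted(m.centroids.tolist())
        assert np.allclose(cents, [[0.0, 0.5], [100.0, 0.5]])
        assert m.labels[0] == m.labels[1] and m.labels[2] == m.labels[3]

    def test_matches_exhaustive_two_partition_optimum(self, rng):
        for _ in range(10):
            X = rng.standard_normal((rng.integers(4, 11), 2))
            m = kmeans_fit(X, 2, seed=5, n_init=50)
            assert m.wcss == pytest.approx(
                brute_force_two_partition_wcss(X), rel=1e-9, abs=1e-9
            )

    def test_wcss_trace_non_increasing(self, rng):
        X = rng.standard_normal((60, 3))
        m = kmeans_fit(X, 4, seed=2, n_init=1)
        assert np.all(np.diff(m.wcss_trace) <= 1e-9)

    def test_wcss_recomputable_and_labels_nearest(self, rng):
        X = rng.standard_normal((40, 4))
        m = kmeans_fit(X, 3, seed=7)
        wcss = ((X - m.centroids[m.labels]) ** 2).sum()
        assert m.wcss == pytest.approx(wcss, rel=1e-12)
        d2 = ((X[:, None, :] - m.centroids[None]) ** 2).sum(axis=2)
        assert np.all(d2[np.arange(len(X)), m.labels] <= d2.min(axis=1) + 1e-9)

    def test_k_greater_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.standard_normal((3, 2)), 4, seed=0)

    def test_agrees_with_sklearn_on_blobs(self, rng):
        """Independent cross-check: same optimum as sklearn KMeans."""
        from sklearn.cluster import KMeans

        centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
        X = np.vstack([c + 0.3 * rng.standard_normal((30, 2)) for c in centers])
        ours = kmeans_fit(X, 3, seed=11, n_init=10)
        sk = KMeans(n_clusters=3, n_init=10, random_state=11).fit(X)
        assert ours.wcss == pytest.approx(sk.inertia_, rel=1e-6)

    def test_determinism(self, rng):
        X = rng.standard_normal((30, 3))
        a = kmeans_fit(X, 3, seed=9)
        b = kmeans_fit(X, 3, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)


class TestElbow:
    def test_worked_synthetic_curve_selects_three(self):
        wcss = np.array([100.0, 40.0, 12.0, 10.5, 10.1, 9.9])
        res = select_knee(np.arange(1, 7), wcss)
        assert res.selected_k == 3
        # discrete curvature diagnostics at interior k
        assert res.curvature_scores[2] == pytest.approx(32.0)
        assert res.curvature_scores[3] == pytest.approx(26.5)
        assert res.curvature_scores[4] == pytest.approx(1.1)
        assert res.curvature_scores[5] == pytest.approx(0.2)

    def test_four_separated_blobs_select_four(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        X = np.vstack([c + 0.2 * rng.standard_normal((25, 2)) for c in centers])
        res = elbow_select(X, 1, 8, seed=4, n_init=10)
        assert res.selected_k == 4

    def test_linear_curve_warns_no_elbow(self, caplog):
        wcss = np.linspace(100.0, 10.0, 8)
        with caplog.at_level("WARNING"):
            res = select_knee(np.arange(1, 9), wcss)
        assert any("no distinct elbow" in r.message for r in caplog.records)
        assert all(abs(v) < 1e-9 for v in res.curvature_scores.values())

    def test_non_monotone_curve_warns(self, caplog):
        wcss = np.array([100.0, 50.0, 60.0, 20.0, 10.0])
        with caplog.at_level("WARNING"):
            select_knee(np.arange(1, 6), wcss)
        assert any("non-increasing" in r.message for r in caplog.records)

    def test_curve_non_increasing_on_real_features(self, scene4_features):
        res = elbow_select(scene4_features, 1, 8, seed=1, n_init=10)
        assert np.all(np.diff(res.wcss_curve) <= 1e-6 * res.wcss_curve[0])

    def test_k_max_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            elbow_select(rng.standard_normal((5, 2)), 1, 10, seed=0)


class TestGMM:
    def test_k1_closed_form(self, rng):
        X = rng.standard_normal((30, 3)) * 2 + 5
        m = gmm_fit(X, 1, seed=0, n_init=1, reg_covar=1e-6)
        assert np.allclose(m.means[0], X.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(X.T, bias=True) + 1e-6 * np.eye(3)
        assert np.allclose(m.covariances[0], ml_cov, atol=1e-8)
        assert m.weights[0] == pytest.approx(1.0)

    def test_loglik_trace_non_decreasing(self, rng):
        for trial in range(5):
            X = rng.standard_normal((40, 2))
            m = gmm_fit(X, 3, seed=trial, n_init=2)
            assert np.all(np.diff(m.loglik_trace) >= -1e-8)

    def test_two_distant_blobs_hard_assignment(self, rng):
        a = rng.standard_normal((25, 2)) * 0.1
        b = rng.standard_normal((25, 2)) * 0.1 + 50.0
        X = np.vstack([a, b])
        m = gmm_fit(X, 2, seed=1, n_init=2)
        resp_max = m.responsibilities.max(axis=1)
        assert np.all(resp_max > 1 - 1e-6)
        means = sorted(m.means.tolist())
        assert np.allclose(means[0], a.mean(axis=0), atol=1e-3)
        assert np.allclose(means[1], b.mean(axis=0), atol=1e-3)

    def test_responsibilities_on_simplex(self, rng):
        X = rng.standard_normal((30, 2))
        m = gmm_fit(X, 3, seed=3, n_init=1)
        assert np.allclose(m.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        assert m.weights.sum() == pytest.approx(1.0)

    def test_matches_kmeans_on_separated_blobs(self, rng):
        from histotex import adjusted_rand_index

        centers = np.array([[0, 0], [12, 0], [0, 12], [12, 12]], dtype=float)
        X = np.vstack([c + 0.2 * rng.standard_normal((20, 2)) for c in centers])
        km = kmeans_fit(X, 4, seed=6)
        gm = gmm_fit(X, 4, seed=6)
        assert adjusted_rand_index(km.labels, gm.labels) == 1.0

    def test_agrees_with_sklearn_loglik(self, rng):
        """Independent cross-check: final log-likelihood close to sklearn's."""
        from sklearn.mixture import GaussianMixture

        X = rng.standard_normal((60, 2))
        X[:30] += 6.0
        ours = gmm_fit(X, 2, seed=2, n_init=5, tol=1e-6)
        sk = GaussianMixture(
            n_components=2, n_init=5, random_state=2, covariance_type="full"
        ).fit(X)
        ours_per_sample = ours.loglik_trace[-1] / len(X)
        assert ours_per_sample == pytest.approx(sk.score(X), abs=5e-3)


class TestPredictLabels:
    def test_training_table_consistency(self, rng):
        X = rng.standard_normal((30, 3))
        km = kmeans_fit(X, 3, seed=4)
        assert np.array_equal(predict_labels(km, X), km.labels)
        gm = gmm_fit(X, 2, seed=4, n_init=2)
        assert np.array_equal(predict_labels(gm, X), gm.labels)

    def test_centroid_point_maps_to_own_label(self, rng):
        X = rng.standard_normal((20, 2))
        km = kmeans_fit(X, 3, seed=5)
        for c in range(3):
            assert predict_labels(km, km.centroids[[c]])[0] == c

    def test_matches_linear_scan_oracle(self, rng):
        X = rng.standard_normal((20, 2))
        km = kmeans_fit(X, 4, seed=8)
        queries = rng.standard_normal((50, 2))
        pred = predict_labels(km, queries)
        for q, p in zip(queries, pred):
            dists = [np.linalg.norm(q - c) for c in km.centroids]
            assert p == int(np.argmin(dists))

    def test_dimension_mismatch_rejected(self, rng):
        km = kmeans_fit(rng.standard_normal((10, 3)), 2, seed=0)
        with pytest.raises(ValueError):
            predict_labels(km, rng.standard_normal((5, 2)))


def test_label_permutation_invariance(rng):
    """Permuting cluster ids changes no quality or agreement index."""
    from histotex import (
        adjusted_rand_index,
        davies_bouldin,
        normalized_mutual_information,
        silhouette_score,
    )

    X = rng.standard_normal((40, 3))
    labels = rng.integers(0, 3, size=40)
    while len(np.unique(labels)) < 3:
        labels = rng.integers(0, 3, size=40)
    perm = np.array([2, 0, 1])
    relabeled = perm[labels]
    other = rng.integers(0, 3, size=40)
    assert silhouette_score(X, relabeled) == pytest.approx(silhouette_score(X, labels))
    assert davies_bouldin(X, relabeled) == pytest.approx(davies_bouldin(X, labels))
    assert adjusted_rand_index(relabeled, other) == pytest.approx(
        adjusted_rand_index(labels, other)
    )
    assert normalized_mutual_information(relabeled, other) == pytest.approx(
        normalized_mutual_information(labels, other)
    )
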