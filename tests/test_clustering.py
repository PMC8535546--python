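"""K-means, BIRCH and affinity propagation against independent oracles."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import AffinityPropagation, KMeans
from sklearn.metrics import adjusted_rand_score

from adherefit.clustering import (
    APState,
    CFTriple,
    ap_fit,
    assign_cluster,
    availability_update,
    birch_fit,
    kmeans_fit,
    responsibility_update,
    similarity_matrix,
    sse_curve,
)


# -- oracles ----------------------------------------------------------------

def brute_force_sse(X, k):
    """Optimal SSE by enumerating every assignment of n points to k labels."""
    X = np.atleast_2d(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(X)):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        sse = 0.0
        for j in range(k):
            pts = X[labels == j]
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def naive_responsibility(S, A):
    n = len(S)
    R = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            R[i, k] = S[i, k] - max(A[i, kp] + S[i, kp] for kp in range(n) if kp != k)
    return R


def naive_availability(R):
    n = len(R)
    A = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            if i == k:
                A[k, k] = sum(max(0.0, R[ip, k]) for ip in range(n) if ip != k)
            else:
                A[i, k] = min(
                    0.0,
                    R[k, k]
                    + sum(max(0.0, R[ip, k]) for ip in range(n) if ip not in (i, k)),
                )
    return A


# -- K-means ----------------------------------------------------------------

class TestKMeans:
    def test_k_distinct_points_fit_perfectly(self):
        X = np.array([[0.0, 0], [10, 0], [0, 10]])
        model = kmeans_fit(X, k=3, seed=0)
        assert model.sse == 0.0

    def test_two_pairs_on_a_line(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = kmeans_fit(X, k=2, seed=0)
        assert sorted(model.centroids.ravel().tolist()) == [0.5, 10.5]
        assert model.sse == pytest.approx(1.0)
        assert model.sse == pytest.approx(brute_force_sse(X, 2))

    @pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (7, 3, 1), (8, 3, 2), (8, 2, 3)])
    def test_attains_brute_force_optimum_on_small_fixtures(self, n, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2)) * 3
        model = kmeans_fit(X, k=k, n_restarts=30, seed=seed)
        assert model.sse == pytest.approx(brute_force_sse(X, k), rel=1e-9)

    def test_sse_non_increasing_within_a_restart(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        model = kmeans_fit(X, k=4, n_restarts=1, seed=4)
        hist = model.sse_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_each_point_assigned_to_nearest_centroid(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        model = kmeans_fit(X, k=3, seed=5)
        d2 = ((X[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        assert np.array_equal(model.labels, d2.argmin(axis=1))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 2))
        a = kmeans_fit(X, k=3, seed=42)
        b = kmeans_fit(X, k=3, seed=42)
        assert np.array_equal(a.centroids, b.centroids) and a.sse == b.sse

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="k must satisfy"):
            kmeans_fit(np.zeros((3, 2)), k=4)

    def test_matches_sklearn_on_separated_blobs(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(c, 0.3, size=(20, 2)) for c in (0, 5, 10)])
        ours = kmeans_fit(X, k=3, seed=7)
        ref = KMeans(n_clusters=3, n_init=10, random_state=7).fit(X)
        assert adjusted_rand_score(ours.labels, ref.labels_) == 1.0
        assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)


class TestSSECurve:
    def test_k_equals_n_gives_zero(self):
        X = np.arange(5.0).reshape(-1, 1)
        curve = dict(sse_curve(X, range(1, 6), seed=0))
        assert curve[5] == 0.0

    def test_non_increasing_when_each_k_is_optimal(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(7, 2))
        curve = sse_curve(X, [1, 2, 3], n_restarts=30, seed=8)
        sses = [s for _, s in curve]
        for (k, s) in curve:
            assert s == pytest.approx(brute_force_sse(X, k), rel=1e-9)
        assert sses == sorted(sses, reverse=True)

    def test_supports_the_3_4_5_cluster_range(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        ks = [k for k, _ in sse_curve(X, [3, 4, 5], seed=9)]
        assert ks == [3, 4, 5]


# -- BIRCH ------------------------------------------------------------------

class TestBirch:
    def test_identical_points_collapse_to_one_cf(self):
        X = np.tile([2.0, 3.0], (8, 1))
        model = birch_fit(X, threshold=0.5, n_global_clusters=3)
        assert len(model.leaf_cfs) == 1
        assert model.leaf_cfs[0].count == 8
        assert np.allclose(model.leaf_cfs[0].centroid, [2.0, 3.0])

    def test_cf_additivity_worked_example(self):
        cf = CFTriple.from_point(np.array([1.0, 0.0])).merged(
            CFTriple.from_point(np.array([0.0, 1.0]))
        )
        assert cf.count == 2
        assert cf.linear_sum.tolist() == [1.0, 1.0]
        assert cf.squared_sum == 2.0
        absorbed = cf.merged(CFTriple.from_point(np.array([1.0, 1.0])))
        assert absorbed.count == 3
        assert absorbed.linear_sum.tolist() == [2.0, 2.0]
        assert absorbed.squared_sum == 4.0

    def test_root_cf_is_sum_of_leaves_conservation(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 50, size=(60, 3)).astype(float)
        model = birch_fit(X, threshold=5.0, branching=4, n_global_clusters=4)
        total = model.root_cf
        assert total.count == 60
        assert np.allclose(total.linear_sum, X.sum(axis=0))
        assert total.squared_sum == pytest.approx((X ** 2).sum())

    def test_every_leaf_respects_the_radius_threshold(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 2)) * 4
        for threshold in (0.001, 0.1, 100.0):
            model = birch_fit(X, threshold=threshold, n_global_clusters=3)
            assert all(cf.radius <= threshold + 1e-12 for cf in model.leaf_cfs)

    def test_recovers_well_separated_clusters(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(c, 0.3, size=(15, 2)) for c in (0, 8, 16)])
        model = birch_fit(X, threshold=1.5, n_global_clusters=3)
        truth = np.repeat([0, 1, 2], 15)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            birch_fit(np.zeros((3, 2)), threshold=0.0)


# -- Affinity propagation ---------------------------------------------------

class TestAffinityPropagation:
    def test_single_point_is_its_own_exemplar(self):
        model = ap_fit(np.array([[3.0, 4.0]]))
        assert model.exemplars.tolist() == [0]
        assert model.labels.tolist() == [0] and model.converged

    def test_first_responsibility_sweep_worked_example(self):
        # 1-D points {0, 1, 5}; median off-diagonal similarity = -16
        S = similarity_matrix(np.array([[0.0], [1.0], [5.0]]), preference="median")
        assert S[0, 0] == -16.0
        R = responsibility_update(S, np.zeros((3, 3)))
        # r(0,1) = s(0,1) - max(s(0,0), s(0,2)) = -1 - (-16) = 15
        assert R[0, 1] == pytest.approx(15.0)

    @pytest.mark.parametrize("n,seed", [(3, 0), (4, 1), (5, 2), (5, 3)])
    def test_sweeps_match_naive_nested_loops(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2)) * 2
        S = similarity_matrix(X)
        A = np.zeros((n, n))
        R = np.zeros((n, n))
        for _ in range(4):
            R_new = responsibility_update(S, A)
            assert np.allclose(R_new, naive_responsibility(S, A), atol=1e-10)
            R = 0.5 * R + 0.5 * R_new
            A_new = availability_update(R)
            assert np.allclose(A_new, naive_availability(R), atol=1e-10)
            A = 0.5 * A + 0.5 * A_new

    def test_criterion_is_r_plus_a_after_fit(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 2))
        model = ap_fit(X, damping=0.7)
        assert np.array_equal(model.C, model.R + model.A)

    def test_uniform_similarities_low_preference_single_cluster(self):
        # equilateral triangle: all pairwise similarities equal
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        model = ap_fit(X, damping=0.5, preference=-10.0)
        assert model.converged
        assert model.n_clusters == 1
        assert set(model.labels.tolist()) == {0}

    def test_damping_outside_half_one_rejected(self):
        X = np.zeros((3, 2))
        for bad in (0.4, 1.0):
            with pytest.raises(ValueError, match="damping"):
                ap_fit(X, damping=bad)

    def test_unconverged_fit_labels_everything_minus_one(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 2))
        model = ap_fit(X, damping=0.5, max_iter=2)
        assert not model.converged
        assert set(model.labels.tolist()) == {-1}
        assert assign_cluster(model, X[0]) == -1

    def test_trajectory_deterministic(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(15, 2))
        a, b = ap_fit(X, damping=0.8), ap_fit(X, damping=0.8)
        assert np.array_equal(a.R, b.R) and np.array_equal(a.labels, b.labels)

    def test_matches_sklearn_on_separated_blobs(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(c, 0.4, size=(10, 2)) for c in (0, 6, 12)])
        ours = ap_fit(X, damping=0.7, preference="median")
        ref = AffinityPropagation(damping=0.7, random_state=0).fit(X)
        assert ours.converged
        assert adjusted_rand_score(ours.labels, ref.labels_) == 1.0


# -- uniform assignment -----------------------------------------------------

class TestAssign:
    def test_vector_equal_to_centroid_maps_to_it(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        model = kmeans_fit(X, k=2, seed=0)
        for j in range(2):
            assert assign_cluster(model, model.centroids[j]) == j

    def test_one_dimensional_boundary(self):
        model = kmeans_fit(np.array([[0.0], [10.0]]), k=2, seed=0)
        lo = int(np.argmin(model.centroids.ravel()))
        assert assign_cluster(model, np.array([4.0])) == lo
        assert assign_cluster(model, np.array([6.0])) == 1 - lo

    def test_birch_assignment_uses_global_leaf_label(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(8, 0.3, (10, 2))])
        model = birch_fit(X, threshold=1.0, n_global_clusters=2)
        assert assign_cluster(model, np.array([0.1, -0.1])) == model.labels[0]
        assert assign_cluster(model, np.array([7.9, 8.2])) == model.labels[10]

    def test_ap_assignment_via_nearest_exemplar(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(6, 0.3, (8, 2))])
        model = ap_fit(X, damping=0.7)
        assert model.converged
        assert assign_cluster(model, np.array([0.0, 0.0])) == model.labels[0]
        assert assign_cluster(model, np.array([6.0, 6.0])) == model.labels[8]

    def test_dimension_mismatch_rejected(self):
        model = kmeans_fit(np.zeros((4, 3)), k=2, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            assign_cluster(model, np.zeros(2))
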