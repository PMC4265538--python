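import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from noduleant.clustering import (
    GAKMeans,
    GaParams,
    ga_refine,
    hierarchical_cluster,
    kmeans_init,
    label_malignancy,
    standardize,
)
from .conftest import partition_of


def two_clouds(seed, n=50, sigma=0.5, separation=10.0):
    """Two gaussian clouds separated by `separation` sigmas."""
    rng = np.random.default_rng(seed)
    a = rng.normal([0.0, 0.0], sigma, size=(n, 2))
    b = rng.normal([separation * sigma, 0.0], sigma, size=(n, 2))
    return np.vstack([a, b]), np.array([0.0, 0.0]), np.array([separation * sigma, 0.0])


def _center_errors(centers, mean_a, mean_b):
    d = np.linalg.norm
    direct = max(d(centers[0] - mean_a), d(centers[1] - mean_b))
    swapped = max(d(centers[0] - mean_b), d(centers[1] - mean_a))
    return min(direct, swapped)


class TestKMeans:
    def test_single_point_single_cluster(self):
        centers = kmeans_init(np.array([[2.0, 3.0]]), k=1, seed=0)
        assert np.allclose(centers, [[2.0, 3.0]])

    def test_recovers_two_separated_clouds(self):
        X, ma, mb = two_clouds(seed=1)
        centers = kmeans_init(X, 2, seed=1)
        assert _center_errors(centers, ma, mb) < 0.25  # 0.5 sigma

    def test_sse_history_non_increasing(self):
        X, *_ = two_clouds(seed=2)
        _, history = kmeans_init(X, 3, seed=2, return_history=True)
        assert all(a >= b - 1e-9 for a, b in zip(history, history[1:]))

    def test_too_many_clusters_raises(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="distinct"):
            kmeans_init(X, 3, seed=0)


class TestGaRefine:
    def test_zero_generations_returns_initializer_unchanged(self):
        X, *_ = two_clouds(seed=3)
        init = kmeans_init(X, 2, seed=3)
        centers, labels, trace = ga_refine(X, init, GaParams(generations=0, seed=3))
        assert np.array_equal(centers, init)
        assert trace.shape == (1,)

    def test_fitness_trace_monotone_and_beats_initializer(self):
        X, *_ = two_clouds(seed=4)
        init = kmeans_init(X, 2, seed=4)
        params = GaParams(population=12, generations=30, seed=4)
        centers, labels, trace = ga_refine(X, init, params)
        assert np.all(np.diff(trace) >= -1e-12)
        init_sse = float(((X[:, None] - init[None]) ** 2).sum(2).min(1).sum())
        best_sse = float(((X[:, None] - centers[None]) ** 2).sum(2).min(1).sum())
        assert best_sse <= init_sse + 1e-9
        assert trace[-1] >= 1.0 / (1.0 + init_sse) - 1e-12

    def test_degenerate_identical_points_warn(self):
        X = np.ones((6, 2))
        with pytest.warns(UserWarning, match="identical"):
            centers, labels, _ = ga_refine(X, np.ones((2, 2)), GaParams(seed=0))
        assert np.allclose(centers, 1.0)
        assert np.array_equal(labels, np.zeros(6))

    def test_assignments_partition_the_points(self):
        X, *_ = two_clouds(seed=5)
        init = kmeans_init(X, 2, seed=5)
        _, labels, _ = ga_refine(X, init, GaParams(generations=10, seed=5))
        assert labels.shape == (100,)
        assert set(labels.tolist()) <= {0, 1}

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GaParams(elitism=20, population=20)
        with pytest.raises(ValueError):
            GaParams(crossover_prob=1.5)


class TestHierarchical:
    def test_k_equals_n_gives_singletons(self):
        X = np.arange(8.0).reshape(4, 2)
        labels = hierarchical_cluster(X, 4)
        assert len(set(labels.tolist())) == 4

    def test_line_points_split_at_the_gap(self):
        X = np.array([[0.0], [1.0], [10.0]])
        labels = hierarchical_cluster(X, 2)
        assert labels[0] == labels[1] != labels[2]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_single_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        k = int(rng.integers(1, n + 1))
        X = rng.random((n, 3))
        ours = hierarchical_cluster(X, k)
        ref = fcluster(linkage(X, method="single"), t=k, criterion="maxclust")
        assert partition_of(ours) == partition_of(ref)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((3, 2)), 4)


class TestLabelMalignancy:
    def test_larger_mean_size_is_malignant(self):
        labels = np.array([0, 0, 1, 1])
        sizes = np.array([30.0, 30.0, 8.0, 8.0])
        intens = np.array([0.5, 0.5, 0.5, 0.5])
        names = label_malignancy(labels, sizes, intens)
        assert names == {0: "malignant", 1: "benign"}

    def test_size_tie_falls_back_to_intensity(self):
        labels = np.array([0, 1])
        names = label_malignancy(labels, np.array([10.0, 10.0]), np.array([0.9, 0.4]))
        assert names == {0: "malignant", 1: "benign"}

    def test_non_binary_clustering_warns(self):
        with pytest.warns(UserWarning):
            names = label_malignancy(np.array([0, 1, 2]), np.ones(3), np.ones(3))
        assert names == {0: "0", 1: "1", 2: "2"}


class TestStandardize:
    def test_zero_mean_unit_spread_constant_columns_zero(self):
        X = np.array([[1.0, 5.0], [3.0, 5.0], [5.0, 5.0]])
        Xs, mean, scale = standardize(X)
        assert np.allclose(Xs[:, 0].mean(), 0.0)
        assert np.allclose(Xs[:, 0].std(), 1.0)
        assert np.allclose(Xs[:, 1], 0.0)
        assert scale[1] == 0.0


class TestGAKMeansEstimator:
    def test_fit_predict_recovers_clouds(self):
        X, ma, mb = two_clouds(seed=6)
        model = GAKMeans(n_clusters=2, generations=20, random_state=6).fit(X)
        assert model.labels_.shape == (100,)
        assert model.fitness_trace_[-1] >= model.fitness_trace_[0] - 1e-12
        # centres are reported in input units
        assert _center_errors(model.cluster_centers_, ma, mb) < 0.25
        assert np.array_equal(model.predict(X), model.labels_)

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        model = GAKMeans(n_clusters=3, generations=5)
        params = model.get_params()
        assert params["n_clusters"] == 3
        cloned = clone(model)
        assert cloned.get_params() == params

    def test_comparable_to_sklearn_kmeans_sse(self):
        from sklearn.cluster import KMeans

        X, *_ = two_clouds(seed=7)
        Xs, _, _ = standardize(X)
        model = GAKMeans(n_clusters=2, generations=30, random_state=7, scale=False).fit(Xs)
        ref = KMeans(n_clusters=2, n_init=5, random_state=7).fit(Xs)
        assert model.inertia_ <= ref.inertia_ * 1.05
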