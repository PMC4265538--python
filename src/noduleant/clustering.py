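"""Benign/malignant grouping of candidate nodules.

The primary clusterer is a genetic-algorithm refinement of k-means: a
chromosome concatenates the k cluster centres (k*d real genes), its
fitness is 1/(1 + SSE) where SSE sums each point's squared distance to its
nearest encoded centre, and the population evolves by tournament
selection, single-point crossover, per-gene Gaussian mutation, and
elitism.  The elite always survives unchanged, so the best fitness trace
is non-decreasing and the returned solution is never worse than its
k-means initializer.  Agglomerative single-linkage clustering is provided
as the comparison method.

Feature columns are standardized (zero mean, unit spread) before any
distance is computed: pixel areas and [0, 1] intensities are
incommensurate, and unstandardized distances would be size-dominated.

With two clusters, the one whose mean (raw) size is larger is labelled
malignant — malignant nodules run larger than benign ones — with mean
intensity breaking ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .features import SHAPE_CODES, FeatureRow

__all__ = [
    "GaParams",
    "standardize",
    "feature_array",
    "kmeans_init",
    "ga_refine",
    "hierarchical_cluster",
    "label_malignancy",
    "GAKMeans",
]


@dataclass(frozen=True)
class GaParams:
    population: int = 20
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1 or self.generations < 0:
            raise ValueError("population must be >= 1 and generations >= 0")
        if not (0.0 <= self.crossover_prob <= 1.0 and 0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("crossover_prob and mutation_prob must lie in [0, 1]")
        if not (0 < self.elitism < self.population):
            raise ValueError("elitism must satisfy 0 < elitism < population")


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each column to zero mean and unit spread.

    Constant columns are left at 0 rather than divided by a zero spread.
    Returns (scaled X, column means, column scales) so results can be
    mapped back to raw units.
    """
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / safe
    Xs[:, scale == 0] = 0.0
    return Xs, mean, scale


def feature_array(rows: list[FeatureRow], use_age: bool = True) -> np.ndarray:
    """Feature rows -> numeric matrix (intensity, size, shape[, age])."""
    cols = [
        [r.mean_intensity for r in rows],
        [float(r.size) for r in rows],
        [SHAPE_CODES[r.shape] for r in rows],
    ]
    if use_age and rows and all(r.age is not None for r in rows):
        cols.append([float(r.age) for r in rows])
    return np.column_stack(cols) if rows else np.empty((0, 3))


def _sse(X: np.ndarray, centers: np.ndarray) -> float:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def kmeans_init(
    X: np.ndarray, k: int, seed: int = 0, return_history: bool = False
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """Lloyd's k-means from k distinct random data points.

    Iterates assignment/update until assignments are stable or 100
    iterations; an emptied cluster is re-seeded with the point farthest
    from its assigned centre.  Requires at least k distinct points.
    ``return_history`` additionally returns the SSE after each update,
    which Lloyd's algorithm makes non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(X, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(f"k={k} exceeds the number of distinct points ({distinct.shape[0]})")
    rng = np.random.default_rng(seed)
    centers = distinct[rng.choice(distinct.shape[0], size=k, replace=False)].copy()
    labels = _assign(X, centers)
    history = [_sse(X, centers)]
    for _ in range(100):
        for j in range(k):
            members = labels == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:
                d2 = ((X - centers[labels]) ** 2).sum(axis=1)
                centers[j] = X[d2.argmax()]
        history.append(_sse(X, centers))
        new_labels = _assign(X, centers)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    if return_history:
        return centers, history
    return centers


def ga_refine(
    X: np.ndarray, init_centers: np.ndarray, params: GaParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Refine cluster centres with a genetic algorithm.

    Returns ``(centers, assignments, fitness_trace)`` where the trace
    holds the best fitness of each generation (index 0 is the initial
    population).  The population starts from the k-means chromosome plus
    Gaussian perturbations of it; elitism guarantees the trace is
    monotone non-decreasing and the result is at least as fit as the
    initializer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    init_centers = np.atleast_2d(np.asarray(init_centers, dtype=np.float64))
    if params is None:
        params = GaParams()
    k, d = init_centers.shape
    n_genes = k * d
    spread = X.std(axis=0)
    spread = np.where(spread > 0, spread, 1.0)
    gene_scale = 0.1 * np.tile(spread, k)

    if np.unique(X, axis=0).shape[0] == 1:
        warnings.warn("all points identical; clustering is degenerate", stacklevel=2)
        centers = np.repeat(X[:1], k, axis=0)
        return centers, np.zeros(X.shape[0], dtype=np.intp), np.full(
            params.generations + 1, 1.0 / (1.0 + _sse(X, centers))
        )

    if params.generations == 0:
        return (
            init_centers,
            _assign(X, init_centers),
            np.array([1.0 / (1.0 + _sse(X, init_centers))]),
        )

    rng = np.random.default_rng(params.seed)
    pop = np.empty((params.population, n_genes))
    pop[0] = init_centers.ravel()
    for i in range(1, params.population):
        pop[i] = pop[0] + rng.normal(0.0, gene_scale)

    def fitness(chromosomes: np.ndarray) -> np.ndarray:
        return np.array(
            [1.0 / (1.0 + _sse(X, ch.reshape(k, d))) for ch in chromosomes]
        )

    fit = fitness(pop)
    trace = np.empty(params.generations + 1)
    trace[0] = fit.max()
    for g in range(params.generations):
        order = np.argsort(-fit, kind="stable")
        new_pop = [pop[i].copy() for i in order[: params.elitism]]
        while len(new_pop) < params.population:
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, params.population, size=2)
                parents.append(pop[a] if fit[a] >= fit[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if n_genes > 1 and rng.random() < params.crossover_prob:
                cut = int(rng.integers(1, n_genes))
                c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
            for child in (c1, c2):
                mask = rng.random(n_genes) < params.mutation_prob
                if mask.any():
                    child[mask] += rng.normal(0.0, gene_scale[mask])
                if len(new_pop) < params.population:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fit = fitness(pop)
        trace[g + 1] = fit.max()
    best = pop[int(np.argmax(fit))].reshape(k, d)
    return best, _assign(X, best), trace


def hierarchical_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative single-linkage (nearest-neighbour) clustering.

    Repeatedly merges the two groups with the smallest nearest-neighbour
    Euclidean dissimilarity until k remain.  Ties are broken toward the
    pair whose (smallest member index, other smallest member index) is
    lexicographically least, so the result is deterministic.  Labels are
    0..k-1 ordered by each cluster's smallest member index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    # Single-link distance between clusters keyed by their min member index.
    while len(clusters) > k:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                link = d[np.ix_(clusters[a], clusters[b])].min()
                cand = (link, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=np.intp)
    for lab, key in enumerate(sorted(clusters)):
        labels[clusters[key]] = lab
    return labels


def label_malignancy(
    assignments: np.ndarray, sizes: np.ndarray, intensities: np.ndarray
) -> dict[int, str]:
    """Label two clusters benign/malignant from raw size and intensity.

    Malignant nodules run larger than benign ones, so the cluster with the
    larger mean size is malignant; equal sizes fall back to the larger
    mean intensity.  With k != 2 the clusters keep their indices as string
    labels (warned) — the dichotomy only makes sense for two groups.
    """
    assignments = np.asarray(assignments)
    ids = np.unique(assignments)
    if ids.size != 2:
        warnings.warn(
            f"malignancy labelling expects 2 clusters, got {ids.size}; "
            "returning cluster indices",
            stacklevel=2,
        )
        return {int(i): str(int(i)) for i in ids}
    sizes = np.asarray(sizes, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    a, b = (int(i) for i in ids)
    mean_sizes = {i: sizes[assignments == i].mean() for i in (a, b)}
    if mean_sizes[a] != mean_sizes[b]:
        malignant = a if mean_sizes[a] > mean_sizes[b] else b
    else:
        mean_int = {i: intensities[assignments == i].mean() for i in (a, b)}
        malignant = a if mean_int[a] >= mean_int[b] else b
    return {i: ("malignant" if i == malignant else "benign") for i in (a, b)}


class GAKMeans(ClusterMixin, BaseEstimator):
    """Genetic-algorithm-refined k-means, scikit-learn style.

    Parameters
    ----------
    n_clusters : number of clusters (2 for the benign/malignant dichotomy).
    population, generations, crossover_prob, mutation_prob, elitism :
        genetic-algorithm knobs, see :class:`GaParams`.
    scale : standardize columns before clustering (recommended whenever
        features mix units).
    random_state : seed for both the k-means initializer and the GA.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (k, d) centres in the *input* units.
    labels_ : cluster index per fitted sample.
    inertia_ : SSE of the fitted solution in standardized space.
    fitness_trace_ : best GA fitness per generation (non-decreasing).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        population: int = 20,
        generations: int = 100,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.05,
        elitism: int = 1,
        scale: bool = True,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.population = population
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism = elitism
        self.scale = scale
        self.random_state = random_state

    def _ga_params(self) -> GaParams:
        return GaParams(
            population=self.population,
            generations=self.generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            elitism=self.elitism,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-D array")
        if self.scale:
            Xs, self.mean_, self.scale_ = standardize(X)
        else:
            Xs = X
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        init = kmeans_init(Xs, self.n_clusters, seed=self.random_state)
        centers, labels, trace = ga_refine(Xs, init, self._ga_params())
        safe = np.where(self.scale_ > 0, self.scale_, 1.0)
        self.cluster_centers_ = centers * safe + self.mean_
        self.labels_ = labels
        self.inertia_ = _sse(Xs, centers)
        self.fitness_trace_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        safe = np.where(self.scale_ > 0, self.scale_, 1.0)
        Xs = (X - self.mean_) / safe
        centers = (self.cluster_centers_ - self.mean_) / safe
        return _assign(Xs, centers)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
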