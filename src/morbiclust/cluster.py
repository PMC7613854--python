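"""Patient clustering algorithms for binary condition data.

Four algorithms are provided, all assigning each patient to exactly one
cluster:

* :class:`~morbiclust.lca.LatentClassAnalysis` — Bernoulli-mixture latent
  class model (model-based);
* :class:`BinaryKMeans` — Lloyd k-means on the raw 0/1 matrix, initial
  centroids drawn as k observations without replacement;
* :class:`MCAKMeans` — tandem approach: multiple correspondence analysis
  to reduce dimension, then k-means on the row coordinates;
* :class:`KMeansHCA` — scalable hybrid: k-means with a large number of
  pre-clusters (default 50), then agglomerative Ward clustering of the
  centroids; each patient inherits the final cluster of its centroid.

Plus the asymmetric binary (Jaccard) distance used for hierarchical
clustering of binary profiles, which ignores joint absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .cohort import validate_binary_matrix
from .lca import LatentClassAnalysis

__all__ = [
    "BinaryKMeans", "MCAKMeans", "KMeansHCA", "ClusteringResult",
    "asymmetric_binary_distance", "pairwise_asymmetric_binary", "hca_ward",
    "make_clusterer", "lca_fit", "kmeans_binary", "mca_kmeans", "kmeans_hca",
    "ALGORITHMS",
]


# ---------------------------------------------------------------------------
# distances and hierarchical clustering
# ---------------------------------------------------------------------------

def asymmetric_binary_distance(a, b) -> float:
    """1 - |A∩B| / |A∪B| over the sets of present conditions.

    Joint absences are ignored, which suits sparse disease data.  Two
    all-zero profiles have an undefined ratio; the distance is defined as
    0 (identical supports) with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both profiles are all-zero; distance defined as 0",
                      UserWarning)
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union


def pairwise_asymmetric_binary(X) -> np.ndarray:
    """Square matrix of asymmetric binary distances between the rows of X."""
    X = np.asarray(X, dtype=bool)
    return squareform(pdist(X, metric="jaccard"))


def hca_ward(distance_matrix: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Uses the squared-update (Ward.D2-style) Lance–Williams recurrence on
    the given distances and cuts the dendrogram at ``k`` clusters.
    Returns 1-based labels.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if k > D.shape[0]:
        raise ValueError(f"cannot cut {D.shape[0]} observations into {k} clusters")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("expected a symmetric non-negative matrix with zero diagonal")
    Z = linkage(squareform(D, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class BinaryKMeans(ClusterMixin, BaseEstimator):
    """Lloyd k-means on the raw 0/1 condition matrix.

    Initial centroids are k observations drawn without replacement; the
    best of ``n_restarts`` initialisations by within-cluster sum of
    squares is kept.  Centroids are continuous (column means), labels are
    hard assignments.
    """

    def __init__(self, n_clusters: int = 4, n_restarts: int = 10,
                 max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_binary_matrix(X)
        if X.shape[0] < self.n_clusters:
            raise ValueError("need at least as many patients as clusters")
        km = KMeans(n_clusters=self.n_clusters, init="random",
                    n_init=self.n_restarts, max_iter=self.max_iter,
                    algorithm="lloyd", random_state=self.random_state).fit(X)
        self.kmeans_ = km
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = km.inertia_
        return self

    def predict(self, X) -> np.ndarray:
        return self.kmeans_.predict(validate_binary_matrix(X))


class MCAKMeans(ClusterMixin, BaseEstimator):
    """Tandem clustering: MCA dimension reduction, then k-means.

    ``n_components=None`` retains K - 1 dimensions (the subspace
    sufficient to separate K centroids); pass ``n_components="inertia"``
    to retain the dimensions covering at least 80% of Benzécri-corrected
    inertia instead.
    """

    def __init__(self, n_clusters: int = 4, n_components=None,
                 n_restarts: int = 10, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _resolve_components(self, mca: "MCA", q: int) -> int:
        from .mca import MCA  # noqa: F401  (type only)
        if self.n_components == "inertia":
            # Benzécri correction: only dimensions with eigenvalue > 1/Q
            # carry real structure; rescale those and keep >= 80% share
            eig = mca.eigenvalues_
            adj = np.where(eig > 1.0 / q, ((q / (q - 1.0)) * (eig - 1.0 / q)) ** 2, 0.0)
            if adj.sum() == 0:
                return 1
            share = np.cumsum(adj) / adj.sum()
            return int(np.searchsorted(share, 0.8) + 1)
        if self.n_components is None:
            return max(self.n_clusters - 1, 1)
        return int(self.n_components)

    def fit(self, X, y=None):
        from .mca import MCA
        X = validate_binary_matrix(X)
        q = X.shape[1]
        with warnings.catch_warnings():
            # the probe requests every dimension; clipping there is expected
            warnings.simplefilter("ignore", UserWarning)
            probe = MCA(n_components=min(X.shape[0], q)).fit(X)
        n_comp = min(self._resolve_components(probe, q), probe.n_components_)
        self.mca_ = MCA(n_components=n_comp).fit(X)
        self.coordinates_ = self.mca_.transform(X)
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_restarts,
                    random_state=self.random_state).fit(self.coordinates_)
        self.kmeans_ = km
        self.labels_ = km.labels_
        self.n_components_ = n_comp
        return self

    def predict(self, X) -> np.ndarray:
        return self.kmeans_.predict(self.mca_.transform(validate_binary_matrix(X)))


class KMeansHCA(ClusterMixin, BaseEstimator):
    """k-means(``n_pre``) followed by Ward clustering of the centroids.

    Hierarchical clustering of every patient is quadratic in N; clustering
    the ``n_pre`` k-means centroids instead scales to large cohorts.  The
    centroid distance is Euclidean by default; ``centroid_metric=
    "asymmetric_binary"`` binarises the centroids at 0.5 and uses the
    asymmetric binary distance (provided for sensitivity analysis).
    """

    def __init__(self, n_clusters: int = 4, n_pre: int = 50,
                 centroid_metric: str = "euclidean", n_restarts: int = 10,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_pre = n_pre
        self.centroid_metric = centroid_metric
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_binary_matrix(X)
        n_pre = min(self.n_pre, X.shape[0])
        if n_pre < self.n_clusters:
            raise ValueError("n_pre must be at least n_clusters")
        stage1 = BinaryKMeans(n_clusters=n_pre, n_restarts=self.n_restarts,
                              random_state=self.random_state).fit(X)
        centroids = stage1.cluster_centers_
        if self.centroid_metric == "euclidean":
            D = squareform(pdist(centroids, metric="euclidean"))
        elif self.centroid_metric == "asymmetric_binary":
            D = pairwise_asymmetric_binary(centroids >= 0.5)
        else:
            raise ValueError(f"unknown centroid_metric {self.centroid_metric!r}")
        centroid_labels = hca_ward(D, self.n_clusters) - 1
        self.stage1_ = stage1
        self.centroid_labels_ = centroid_labels
        self.labels_ = centroid_labels[stage1.labels_]
        return self

    def predict(self, X) -> np.ndarray:
        return self.centroid_labels_[self.stage1_.predict(X)]


# ---------------------------------------------------------------------------
# functional layer
# ---------------------------------------------------------------------------

ALGORITHMS = ("lca", "kmeans", "mca_kmeans", "kmeans_hca")


def make_clusterer(algorithm: str, k: int, random_state: int | None = None,
                   **kwargs) -> BaseEstimator:
    """Construct one of the four clusterers by name at the requested K."""
    if algorithm == "lca":
        return LatentClassAnalysis(n_classes=k, random_state=random_state, **kwargs)
    if algorithm == "kmeans":
        return BinaryKMeans(n_clusters=k, random_state=random_state, **kwargs)
    if algorithm == "mca_kmeans":
        return MCAKMeans(n_clusters=k, random_state=random_state, **kwargs)
    if algorithm == "kmeans_hca":
        return KMeansHCA(n_clusters=k, random_state=random_state, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ClusteringResult:
    """A hard partition of a cohort by one algorithm."""

    labels: np.ndarray
    k: int
    algorithm: str
    seed: Optional[int] = None
    model: Optional[BaseEstimator] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.labels)) > self.k:
            raise ValueError("more distinct labels than requested clusters")


def _run(algorithm: str, cohort, k: int, seed: int | None, **kwargs) -> ClusteringResult:
    est = make_clusterer(algorithm, k, random_state=seed, **kwargs)
    est.fit(cohort)
    return ClusteringResult(labels=est.labels_, k=k, algorithm=algorithm,
                            seed=seed, model=est)


def lca_fit(cohort, k: int, n_restarts: int = 10, tol: float = 1e-6,
            max_iter: int = 500, seed: int | None = None) -> ClusteringResult:
    """Fit latent class analysis and return its hard modal-class partition."""
    return _run("lca", cohort, k, seed, n_restarts=n_restarts, tol=tol,
                max_iter=max_iter)


def kmeans_binary(cohort, k: int, n_restarts: int = 10,
                  seed: int | None = None) -> ClusteringResult:
    return _run("kmeans", cohort, k, seed, n_restarts=n_restarts)


def mca_kmeans(cohort, k: int, n_components=None,
               seed: int | None = None) -> ClusteringResult:
    return _run("mca_kmeans", cohort, k, seed, n_components=n_components)


def kmeans_hca(cohort, k: int, n_pre: int = 50,
               seed: int | None = None) -> ClusteringResult:
    return _run("kmeans_hca", cohort, k, seed, n_pre=n_pre)
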