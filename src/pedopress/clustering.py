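"""Clustering algorithms and internal validity indices.

Implements the unsupervised toolbox used to explore plantar-pressure
feature sets: the standard distance metrics (euclidean, manhattan,
cosine, jaccard), z-score standardization, seeded Lloyd k-means with
k-means++ initialization and a recorded inertia trace, the elbow
diagnostic, agglomerative hierarchical clustering with dendrogram
cutting, and three internal validity indices — silhouette,
Davies–Bouldin, and Dunn.

The Dunn index ships in two variants. ``standard`` is the textbook
definition: minimum between-cluster point distance divided by the
maximum intra-cluster diameter (higher is better). ``paper`` evaluates
an alternative summation form sometimes printed in the applied
literature,

    DI = (1/n_c) * sum_i max_{j != i} (r_i + r_j) / d(c_i, c_j),

with ``r_i`` the mean member-to-centroid distance — structurally the
Davies–Bouldin expression. Both are reported so results remain
comparable either way; ``standard`` is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

__all__ = [
    "UndefinedDistanceError",
    "DegenerateColumnError",
    "Dendrogram",
    "KMeansResult",
    "ClusterQualityReport",
    "distance",
    "pairwise_distances",
    "standardize",
    "kmeans",
    "elbow_curve",
    "agglomerative",
    "silhouette_score",
    "davies_bouldin",
    "dunn_index",
    "cluster_quality_report",
]

METRICS = ("euclidean", "manhattan", "cosine", "jaccard")
LINKAGES = ("single", "complete", "average", "ward")


class UndefinedDistanceError(ValueError):
    """Distance is mathematically undefined for the given inputs."""


class DegenerateColumnError(ValueError):
    """A feature column has zero spread and cannot be standardized."""


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    return labels, uniq


def distance(x, y, metric: str = "euclidean") -> float:
    """Distance between two vectors under one of the standard metrics.

    Cosine distance is 1 − cosine similarity (a lone zero vector is at
    distance 1 from everything; two zero vectors are undefined).
    Jaccard binarizes both vectors (nonzero → 1) and returns
    1 − |intersection| / |union|.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal dimension")
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "manhattan":
        return float(np.abs(x - y).sum())
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 and ny == 0:
            raise UndefinedDistanceError("cosine distance undefined for two zero vectors")
        if nx == 0 or ny == 0:
            return 1.0
        return float(1.0 - np.dot(x, y) / (nx * ny))
    if metric == "jaccard":
        bx, by = x != 0, y != 0
        union = np.logical_or(bx, by).sum()
        if union == 0:
            return 0.0
        return float(1.0 - np.logical_and(bx, by).sum() / union)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


_CDIST_NAME = {"euclidean": "euclidean", "manhattan": "cityblock", "cosine": "cosine"}


def pairwise_distances(points: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Full n×n distance matrix under the given metric."""
    points = np.asarray(points, dtype=np.float64)
    if metric in _CDIST_NAME:
        d = cdist(points, points, _CDIST_NAME[metric])
        if metric == "cosine" and np.isnan(d).any():
            zeros = ~points.any(axis=1)
            if zeros.sum() >= 2:
                raise UndefinedDistanceError("cosine distance undefined for two zero vectors")
            d = np.nan_to_num(d, nan=1.0)
        return d
    if metric == "jaccard":
        d = cdist(points != 0, points != 0, "jaccard")
        return np.nan_to_num(d, nan=0.0)  # two all-zero vectors: empty union -> 0
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def standardize(points: np.ndarray) -> np.ndarray:
    """Z-score each column: mean 0, population standard deviation 1."""
    points = np.asarray(points, dtype=np.float64)
    sd = points.std(axis=0)  # population convention (ddof=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise DegenerateColumnError(f"column(s) {bad.tolist()} constant; cannot standardize")
    return (points - points.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# k-means


@dataclass(frozen=True)
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    n_iter: int
    inertia_trace: tuple[float, ...]  # inertia after each assignment step
    seed: int


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    closest = ((points - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = closest.sum()
        if total == 0:
            centroids[i] = points[rng.integers(n)]
        else:
            centroids[i] = points[rng.choice(n, p=closest / total)]
        closest = np.minimum(closest, ((points - centroids[i]) ** 2).sum(axis=1))
    return centroids


def _lloyd(
    points: np.ndarray,
    centroids: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    k = centroids.shape[0]
    trace: list[float] = []
    labels = np.zeros(points.shape[0], dtype=np.intp)
    for it in range(1, max_iter + 1):
        sq = cdist(points, centroids, "sqeuclidean")
        labels = sq.argmin(axis=1)  # argmin -> lowest centroid index on ties
        trace.append(float(sq[np.arange(len(labels)), labels].sum()))
        new_centroids = centroids.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centroids[j] = points[members].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its own centroid
                dist_to_own = sq[np.arange(len(labels)), labels]
                far = int(dist_to_own.argmax())
                new_centroids[j] = points[far]
                labels[far] = j
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        if shift < tol:
            break
    sq = cdist(points, centroids, "sqeuclidean")
    labels = sq.argmin(axis=1)
    inertia = float(sq[np.arange(len(labels)), labels].sum())
    trace.append(inertia)
    return labels, centroids, inertia, it, trace


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
    init_centroids: np.ndarray | None = None,
) -> KMeansResult:
    """Seeded Lloyd k-means with k-means++ initialization.

    Assignment ties break toward the lowest centroid index; an empty
    cluster is re-seeded to the point farthest from its assigned
    centroid; iteration stops when the largest centroid shift drops
    below ``tol``. The inertia after every assignment step is recorded
    in ``inertia_trace`` (non-increasing by construction of Lloyd's
    algorithm).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be an n x d array")
    n = points.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    if init_centroids is None:
        init_centroids = _kmeanspp_init(points, k, rng)
    labels, centroids, inertia, n_iter, trace = _lloyd(points, init_centroids, max_iter, tol)
    return KMeansResult(labels, centroids, inertia, n_iter, tuple(trace), seed)


def elbow_curve(
    points: np.ndarray,
    k_range,
    seed: int = 0,
    restarts: int = 5,
) -> list[tuple[int, float]]:
    """Best-of-``restarts`` k-means inertia for each k.

    One restart per k is warm-started from the previous k's best
    centroids plus the point farthest from them, which guarantees the
    returned inertia is non-increasing in k; that monotonicity is
    asserted before returning.
    """
    points = np.asarray(points, dtype=np.float64)
    ks = sorted(set(int(k) for k in k_range))
    curve: list[tuple[int, float]] = []
    prev_best: KMeansResult | None = None
    for i, k in enumerate(ks):
        best: KMeansResult | None = None
        for r in range(restarts):
            res = kmeans(points, k, seed=seed * 10007 + k * 101 + r)
            if best is None or res.inertia < best.inertia:
                best = res
        if prev_best is not None and prev_best.centroids.shape[0] == k - 1:
            d = cdist(points, prev_best.centroids, "sqeuclidean").min(axis=1)
            warm = np.vstack([prev_best.centroids, points[int(d.argmax())]])
            res = kmeans(points, k, seed=seed, init_centroids=warm)
            if res.inertia < best.inertia:
                best = res
        curve.append((k, best.inertia))
        prev_best = best
    inertias = [v for _, v in curve]
    assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:])), (
        "elbow curve not monotone"
    )
    return curve


# ---------------------------------------------------------------------------
# agglomerative hierarchical clustering


@dataclass(frozen=True)
class Dendrogram:
    """Merge history of an agglomerative run.

    ``merges`` has one row per merge, ``(cluster_a, cluster_b, height,
    new_size)``, in scipy linkage-matrix convention (original points
    are clusters 0..n-1; the i-th merge creates cluster n+i).
    """

    merges: np.ndarray = field(repr=False)
    linkage_name: str
    metric: str
    n: int

    def cut(self, k: int) -> np.ndarray:
        """Labels 0..k-1 from cutting the tree into k clusters."""
        if not 1 <= k <= self.n:
            raise ValueError("k must be in [1, n]")
        raw = fcluster(self.merges, t=k, criterion="maxclust")
        _, labels = np.unique(raw, return_inverse=True)
        return labels


def agglomerative(points: np.ndarray, linkage_name: str = "ward", metric: str = "euclidean") -> Dendrogram:
    """Bottom-up hierarchical clustering; Ward requires euclidean."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need an n x d array with n >= 2")
    if linkage_name not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage_name!r}; expected one of {LINKAGES}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if linkage_name == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    if metric == "jaccard":
        merges = linkage(np.asarray(points != 0, dtype=bool), method=linkage_name, metric="jaccard")
    else:
        merges = linkage(points, method=linkage_name, metric=_CDIST_NAME[metric])
    return Dendrogram(merges, linkage_name, metric, points.shape[0])


# ---------------------------------------------------------------------------
# internal validity indices


@dataclass(frozen=True)
class ClusterQualityReport:
    silhouette: float
    davies_bouldin: float
    dunn_standard: float
    dunn_paper_variant: float
    metric: str
    n: int
    k: int

    def as_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
            "dunn_standard": self.dunn_standard if math.isfinite(self.dunn_standard) else "inf",
            "dunn_paper_variant": self.dunn_paper_variant,
            "metric": self.metric,
            "n": self.n,
            "k": self.k,
        }


def silhouette_score(points, labels, metric: str = "euclidean") -> tuple[np.ndarray, float]:
    """Per-point silhouette values s(i) = (b−a)/max(a,b) and their mean.

    a(i) is the mean distance to the other members of i's cluster, b(i)
    the smallest mean distance to any other cluster. Points in
    singleton clusters get s(i) = 0; coincident clusters (a = b) also
    give 0.
    """
    points = np.asarray(points, dtype=np.float64)
    labels, uniq = _check_labels(labels)
    d = pairwise_distances(points, metric)
    n = points.shape[0]
    s = np.zeros(n)
    members = {c: np.nonzero(labels == c)[0] for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            continue  # singleton convention: s = 0
        a = d[i, own].sum() / (own.size - 1)
        b = min(d[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def _centroids_and_radii(points: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    cents = np.array([points[labels == c].mean(axis=0) for c in uniq])
    radii = np.array(
        [np.linalg.norm(points[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    return cents, radii


def davies_bouldin(points, labels) -> float:
    """Davies–Bouldin index: mean over clusters of the worst
    (r_i + r_j) / d(c_i, c_j) similarity to another cluster; lower is
    better. Radii are mean euclidean member-to-centroid distances."""
    points = np.asarray(points, dtype=np.float64)
    labels, uniq = _check_labels(labels)
    cents, radii = _centroids_and_radii(points, labels, uniq)
    cd = cdist(cents, cents)
    k = uniq.size
    worst = np.empty(k)
    for i in range(k):
        ratios = [
            (radii[i] + radii[j]) / cd[i, j] if cd[i, j] > 0 else None
            for j in range(k)
            if j != i
        ]
        if any(r is None for r in ratios):
            raise ZeroDivisionError("coincident cluster centroids; DBI undefined")
        worst[i] = max(ratios)
    return float(worst.mean())


def dunn_index(points, labels, variant: str = "standard", metric: str = "euclidean") -> float:
    """Dunn index in either the standard or the summation ("paper") form.

    standard: min between-cluster point distance / max intra-cluster
    diameter (higher is better); all-singleton clusterings have zero
    diameters and return ``inf``. paper: the DBI-like summation over
    centroid distances and mean member-to-centroid radii described in
    the module docstring.
    """
    points = np.asarray(points, dtype=np.float64)
    labels, uniq = _check_labels(labels)
    if variant == "standard":
        d = pairwise_distances(points, metric)
        inter = math.inf
        diam = 0.0
        for a in range(uniq.size):
            ia = np.nonzero(labels == uniq[a])[0]
            block = d[np.ix_(ia, ia)]
            diam = max(diam, float(block.max()))
            for b in range(a + 1, uniq.size):
                ib = np.nonzero(labels == uniq[b])[0]
                inter = min(inter, float(d[np.ix_(ia, ib)].min()))
        if diam == 0.0:
            return math.inf
        return inter / diam
    if variant == "paper":
        cents, radii = _centroids_and_radii(points, labels, uniq)
        cd = cdist(cents, cents)
        k = uniq.size
        total = 0.0
        for i in range(k):
            ratios = [
                (radii[i] + radii[j]) / cd[i, j] for j in range(k) if j != i and cd[i, j] > 0
            ]
            if len(ratios) < k - 1:
                raise ZeroDivisionError("coincident cluster centroids; index undefined")
            total += max(ratios)
        return total / k
    raise ValueError(f"unknown Dunn variant {variant!r}; expected 'standard' or 'paper'")


def cluster_quality_report(points, labels, metric: str = "euclidean") -> ClusterQualityReport:
    """All internal validity indices for one labeled point set."""
    points = np.asarray(points, dtype=np.float64)
    labels_arr, uniq = _check_labels(labels)
    _, sil = silhouette_score(points, labels_arr, metric)
    return ClusterQualityReport(
        silhouette=sil,
        davies_bouldin=davies_bouldin(points, labels_arr),
        dunn_standard=dunn_index(points, labels_arr, "standard", metric),
        dunn_paper_variant=dunn_index(points, labels_arr, "paper", metric),
        metric=metric,
        n=points.shape[0],
        k=uniq.size,
    )
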