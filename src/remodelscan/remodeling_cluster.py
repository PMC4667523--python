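"""k-means partitioning of summit-anchored delta profiles.

The number of clusters is estimated from the total within-cluster
sum-of-squares (WSS) curve over a range of k (default 5-80), taking the
point of maximum discrete curvature as the suggested elbow; the partition
itself is plain Euclidean k-means with k-means++ starts, best of several
restarts, reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .profile_matrix import ProfileMatrix

__all__ = ["ClusterResult", "KCurve", "estimate_k", "kmeans_cluster", "DEFAULT_SEED"]

#: Default RNG seed recorded in every result; override per run.
DEFAULT_SEED = 1729


@dataclass
class ClusterResult:
    """A k-means partition of matrix rows.

    Clusters are re-indexed by descending size (ties by original index) so
    cluster 0 is always the largest, making reports stable across runs.
    """

    labels: np.ndarray
    centroids: np.ndarray
    wss: float
    seed: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def recompute_wss(self, matrix: ProfileMatrix) -> float:
        """Independent WSS recomputation from labels and centroids."""
        diff = matrix.values - self.centroids[self.labels]
        return float((diff ** 2).sum())


@dataclass
class KCurve:
    """WSS-vs-k curve with the maximum-curvature elbow suggestion."""

    k_values: np.ndarray
    wss_values: np.ndarray
    suggested_k: int


def _row_zscale(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mean) / sd


def _fit_kmeans(values: np.ndarray, k: int, restarts: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed, algorithm="lloyd")
    km.fit(values)
    return km


def estimate_k(matrix: ProfileMatrix, k_min: int = 5, k_max: int = 80,
               restarts: int = 3, seed: int = DEFAULT_SEED,
               row_scale: bool = False) -> KCurve:
    """Compute the WSS curve for k in [k_min, k_max] and suggest an elbow.

    WSS at each k is the best of ``restarts`` k-means++ runs.  The suggested
    k maximizes the discrete second difference of the WSS curve (a
    kneedle-style maximum-curvature rule); it is a suggestion — the partition
    step accepts any k.
    """
    if matrix.n_sites <= k_max:
        raise ValueError(
            f"matrix has {matrix.n_sites} rows <= k_max={k_max}; "
            "choose a smaller k_max")
    if k_min < 2 or k_min >= k_max:
        raise ValueError("need 2 <= k_min < k_max")
    values = _row_zscale(matrix.values) if row_scale else matrix.values
    ks = np.arange(k_min, k_max + 1)
    wss = np.array([_fit_kmeans(values, int(k), restarts, seed).inertia_
                    for k in ks])
    # enforce monotone non-increase against restart noise before curvature
    wss_mono = np.minimum.accumulate(wss)
    if len(ks) >= 3:
        curvature = wss_mono[:-2] - 2 * wss_mono[1:-1] + wss_mono[2:]
        suggested = int(ks[1:-1][np.argmax(curvature)])
    else:
        suggested = int(ks[0])
    return KCurve(ks, wss, suggested)


def kmeans_cluster(matrix: ProfileMatrix, k: int = 27, restarts: int = 10,
                   seed: int = DEFAULT_SEED, row_scale: bool = False) -> ClusterResult:
    """Partition matrix rows into k clusters (default k = 27).

    Rows are clustered on raw delta values by default; ``row_scale=True``
    z-scales each row first (shape-only clustering).  Deterministic for a
    fixed seed; clusters are re-indexed by descending size.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.n_sites <= k:
        raise ValueError(f"matrix has {matrix.n_sites} rows <= k={k}")
    values = _row_zscale(matrix.values) if row_scale else matrix.values
    km = _fit_kmeans(values, k, restarts, seed)
    raw_labels = km.labels_.astype(np.int64)
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    labels = remap[raw_labels]
    # centroids on the *input* scale used for clustering
    centroids = km.cluster_centers_[order]
    return ClusterResult(labels=labels, centroids=centroids,
                         wss=float(km.inertia_), seed=seed)
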