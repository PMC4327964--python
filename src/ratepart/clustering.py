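"""k-means (k = 2) on site-rate vectors.

A thin, defensively wrapped layer over scikit-learn's Lloyd k-means with
k-means++ seeding and 100 restarts, which is the configuration the
iterative partitioner relies on: the restart winner is the run with the
smallest within-cluster sum of squares (WCSS).  Degenerate inputs (fewer
distinct points than clusters) come back flagged rather than raising, so
the partitioner can treat "no valid split" as an ordinary decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans, kmeans_plusplus

__all__ = ["ClusteringResult", "kmeans_pp_init", "kmeans"]


@dataclass
class ClusteringResult:
    """Labels, centroids and WCSS of the best restart."""

    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    degenerate: bool


def _as_matrix(points) -> np.ndarray:
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _rng_to_seed(rng: np.random.Generator | int | None) -> int | None:
    if rng is None:
        return None
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    return int(rng.integers(0, 2**31 - 1))


def kmeans_pp_init(
    points, k: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """k-means++ seeding: first centroid uniform, later centroids sampled
    proportionally to squared distance from the nearest chosen centroid.
    Returned centroids are members of the input point set."""
    X = _as_matrix(points)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct points for k-means++ seeding")
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=_rng_to_seed(rng))
    return centers


def kmeans(
    points,
    k: int = 2,
    n_init: int = 100,
    tol: float = 1e-8,
    rng: np.random.Generator | int | None = None,
) -> ClusteringResult:
    """Best-of-``n_init`` Lloyd k-means with k-means++ seeding.

    All-identical input (or fewer distinct points than k) yields a
    degenerate single-cluster result instead of an exception.
    """
    X = _as_matrix(points)
    if X.shape[0] < 2:
        raise ValueError("k-means needs at least two points")
    if np.unique(X, axis=0).shape[0] < k:
        return ClusteringResult(
            labels=np.zeros(X.shape[0], dtype=int),
            centroids=X.mean(axis=0, keepdims=True),
            wcss=float(((X - X.mean(axis=0)) ** 2).sum()),
            degenerate=True,
        )
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, tol=tol,
        algorithm="lloyd", random_state=_rng_to_seed(rng),
    ).fit(X)
    return ClusteringResult(
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        degenerate=len(np.unique(km.labels_)) < k,
    )
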