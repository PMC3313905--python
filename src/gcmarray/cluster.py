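"""Cluster analysis of expression profiles.

Genes are first screened by standard deviation across experiments (top
100, "SD100"), then partitioned by restarted k-means with squared
Euclidean distance.  Model selection scans k over a range, recording
for each k the best average silhouette width over many random restarts,
and picks the k maximizing that curve (smallest k on ties).

k-means is implemented here (Lloyd's algorithm with random data-point
seeding) because the selection protocol needs every restart's
within-cluster SSE and silhouette, not just the single best run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterResult",
    "select_high_variance",
    "kmeans_best_of",
    "silhouette_mean",
    "select_optimal_k",
    "pairwise_sqeuclidean",
]


@dataclass
class ClusterResult:
    """One accepted clustering plus its quality measures."""

    assignment: np.ndarray  # cluster index per point
    centroids: np.ndarray
    within_sse: float
    silhouettes: np.ndarray
    mean_silhouette: float
    restart_sse: np.ndarray = field(default_factory=lambda: np.empty(0))
    gene_id: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        gid = self.gene_id
        if gid is None:
            gid = np.arange(self.assignment.size)
        return pd.DataFrame({"gene_id": gid, "cluster": self.assignment + 1})


def select_high_variance(matrix: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """Top-n genes by sample SD (ddof=1) across experiments.

    Ties are broken by gene_id so the selection is deterministic.
    """
    if n > len(matrix):
        raise ValueError(f"requested {n} genes but matrix has {len(matrix)}")
    sd = matrix.std(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-sd[g], str(g)))
    return matrix.loc[order[:n]]


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    """One Lloyd's k-means run seeded from k distinct data points."""
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            members = new_labels == c
            if not members.any():
                # re-seed an emptied cluster with the point farthest
                # from its current centroid
                far = d2[np.arange(n), new_labels].argmax()
                centroids[c] = X[far]
                new_labels[far] = c
                members = new_labels == c
            centroids[c] = X[members].mean(axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    d2 = ((X - centroids[labels]) ** 2).sum(axis=1)
    return labels, centroids, float(d2.sum())


def pairwise_sqeuclidean(X: np.ndarray) -> np.ndarray:
    sq = (X**2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _silhouettes_from_D(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette widths S_i = (b_i - a_i)/max(a_i, b_i) from a
    precomputed distance matrix; singletons get S_i = 0."""
    n = D.shape[0]
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("silhouettes require at least 2 clusters")
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in ks], axis=1)
    counts = np.array([(labels == c).sum() for c in ks])
    pos = np.searchsorted(ks, labels)
    own_count = counts[pos]
    S = np.zeros(n)
    own_sum = sums[np.arange(n), pos]
    with np.errstate(invalid="ignore"):
        a = np.where(own_count > 1, own_sum / np.maximum(own_count - 1, 1), 0.0)
    other = sums / counts[None, :]
    other[np.arange(n), pos] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    nz = (denom > 0) & (own_count > 1)
    S[nz] = (b[nz] - a[nz]) / denom[nz]
    return S


def silhouette_mean(
    X: np.ndarray, assignment: np.ndarray, D: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths and their mean, squared-Euclidean
    metric.  Degenerate points with a_i = b_i = 0 score 0."""
    if D is None:
        D = pairwise_sqeuclidean(np.asarray(X, dtype=float))
    S = _silhouettes_from_D(D, np.asarray(assignment))
    return S, float(S.mean())


def kmeans_best_of(
    matrix: pd.DataFrame | np.ndarray,
    k: int,
    n_init: int = 100,
    seed: int | None = None,
) -> ClusterResult:
    """Best of ``n_init`` restarted k-means runs by within-cluster SSE.

    Each restart seeds centroids at k distinct random data points; the
    run minimizing the sum over clusters of within-cluster squared
    point-to-centroid distances wins.  All restart scores are retained.
    """
    gene_id = None
    if isinstance(matrix, pd.DataFrame):
        gene_id = matrix.index.to_numpy()
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    scores = np.empty(n_init)
    for r in range(n_init):
        labels, centroids, sse = _lloyd(X, k, rng)
        scores[r] = sse
        if best is None or sse < best[2]:
            best = (labels, centroids, sse)
    labels, centroids, sse = best
    if k < n:
        S, S_bar = silhouette_mean(X, labels)
    else:  # every point its own cluster: SSE 0, silhouettes all 0
        S, S_bar = np.zeros(n), 0.0
    return ClusterResult(
        assignment=labels,
        centroids=centroids,
        within_sse=sse,
        silhouettes=S,
        mean_silhouette=S_bar,
        restart_sse=scores,
        gene_id=gene_id,
    )


def select_optimal_k(
    matrix: pd.DataFrame | np.ndarray,
    k_min: int = 2,
    k_max: int = 30,
    n_init: int = 1000,
    seed: int | None = None,
) -> tuple[int, pd.Series]:
    """Scan k, recording the best mean silhouette over restarts per k.

    Returns (k*, curve) where k* maximizes the curve of best average
    silhouette widths (ties go to the smallest k).
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not (2 <= k_min <= k_max < n):
        raise ValueError(f"need 2 <= k_min <= k_max < n_points={n}")
    rng = np.random.default_rng(seed)
    D = pairwise_sqeuclidean(X)
    curve = {}
    for k in range(k_min, k_max + 1):
        best_s = -np.inf
        for _ in range(n_init):
            labels, _, _ = _lloyd(X, k, rng)
            if np.unique(labels).size < 2:
                continue
            s = float(_silhouettes_from_D(D, labels).mean())
            if s > best_s:
                best_s = s
        curve[k] = best_s
    curve = pd.Series(curve, name="best_mean_silhouette")
    k_star = int(curve.idxmax())  # idxmax returns the first (smallest) max
    return k_star, curve
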