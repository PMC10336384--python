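"""Delay-coordinate reconstruction and neighbor queries.

The embedding convention is backward, most-recent-first: the point for
time t (0-based) is (s_t, s_{t−lag}, ..., s_{t−(dim−1)·lag}), so the
first valid time index is (dim−1)·lag and the cloud has
L − (dim−1)·lag points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError

__all__ = ["EmbeddingParams", "DelayEmbedding", "delay_embed", "select_lag",
           "nearest_neighbors", "autocorrelation"]


@dataclass(frozen=True)
class EmbeddingParams:
    dim: int = 2
    lag: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise DataError("embedding dimension must be >= 1")
        if self.lag < 1:
            raise DataError("embedding lag must be >= 1")

    @property
    def window(self) -> int:
        """Samples consumed by one embedding vector: (dim−1)·lag."""
        return (self.dim - 1) * self.lag


@dataclass
class DelayEmbedding:
    points: np.ndarray       # (n_points, dim)
    time_index: np.ndarray   # original sample index of each row
    params: EmbeddingParams

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def delay_embed(series: np.ndarray, params: EmbeddingParams) -> DelayEmbedding:
    """Reconstruct the attractor from one scalar channel."""
    s = np.ascontiguousarray(series, dtype=float)
    if s.ndim != 1:
        raise DataError("delay_embed expects a single channel")
    L = len(s)
    w = params.window
    if L <= w:
        raise DataError(
            f"series of length {L} too short for dim={params.dim}, "
            f"lag={params.lag}; need at least {w + 1} samples"
        )
    n = L - w
    points = np.empty((n, params.dim))
    for k in range(params.dim):
        offset = w - k * params.lag
        points[:, k] = s[offset : offset + n]
    return DelayEmbedding(points, np.arange(w, L), params)


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag."""
    x = np.asarray(series, float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise DataError("constant series has no autocorrelation")
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = float(x[:-k] @ x[k:]) / denom
    return acf


def select_lag(series: np.ndarray, max_lag: int | None = None) -> int:
    """Data-driven delay: the earlier of the first local minimum of the
    autocorrelation function and its first drop below 1/e, falling back
    to 1 when neither occurs within ``max_lag``."""
    x = np.asarray(series, float)
    if max_lag is None:
        max_lag = min(100, len(x) // 2 - 1)
    if len(x) <= 2 * max_lag:
        max_lag = max(1, len(x) // 2 - 1)
    acf = autocorrelation(x, max_lag)
    first_min = None
    for k in range(1, max_lag):
        if acf[k] < acf[k - 1] and acf[k] <= acf[k + 1]:
            first_min = k
            break
    below = np.flatnonzero(acf[1:] < 1.0 / np.e)
    first_below = int(below[0]) + 1 if below.size else None
    candidates = [c for c in (first_min, first_below) if c is not None]
    return min(candidates) if candidates else 1


def nearest_neighbors(
    embedding: DelayEmbedding, k: int, theiler: int = 0
):
    """k nearest points (Euclidean) of every point in the cloud, the
    point itself excluded, neighbors with |t_i − t_j| <= theiler
    excluded, ties broken by lower time index.

    Returns (indices (n, k), distances (n, k)) as row indices into
    ``embedding.points``.
    """
    pts = embedding.points
    t = embedding.time_index
    n = pts.shape[0]
    if k >= n:
        raise DataError(f"k={k} neighbors requested from {n} points")
    if n <= 2000:
        # exact brute force with deterministic tie-breaking
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        excl = np.abs(t[:, None] - t[None, :]) <= theiler
        d[excl] = np.inf
        order = np.lexsort((np.broadcast_to(t, (n, n)), d), axis=1)
        idx = order[:, :k]
        dist = np.take_along_axis(d, idx, axis=1)
        if not np.isfinite(dist).all():
            raise DataError("Theiler window leaves fewer than k neighbors")
        return idx, dist
    tree = cKDTree(pts)
    extra = 2 * theiler + 1
    dist_all, idx_all = tree.query(pts, k=k + extra)
    idx = np.empty((n, k), dtype=int)
    dist = np.empty((n, k))
    for i in range(n):
        keep = np.abs(t[idx_all[i]] - t[i]) > theiler
        sel = np.flatnonzero(keep)[:k]
        if sel.size < k:
            raise DataError("Theiler window leaves fewer than k neighbors")
        idx[i] = idx_all[i, sel]
        dist[i] = dist_all[i, sel]
    return idx, dist
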