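"""Information-theoretic diagnostics: Pearson correlation, the
Kraskov–Stögbauer–Grassberger (KSG) k-NN mutual-information estimator
(algorithm 1) and the Kozachenko–Leonenko (KL) nearest-neighbor
differential-entropy estimator.  All values are in nats; neighborhoods
use the max-norm; a deterministic jitter at 1e-10 of the sample scale
breaks ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import pearsonr

from .errors import DataError

__all__ = ["EstimatorSpec", "ksg_mi", "kl_entropy", "correlation"]


@dataclass(frozen=True)
class EstimatorSpec:
    """Neighbor count for the k-NN estimators (max-norm metric)."""

    k: int = 4


def _jitter(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scale = float(np.std(x))
    if scale == 0.0:
        scale = 1.0
    return x + rng.normal(0.0, 1e-10 * scale, size=x.shape)


def ksg_mi(x: np.ndarray, y: np.ndarray, spec: EstimatorSpec = EstimatorSpec(),
           seed: int = 0) -> float:
    """KSG mutual information between two scalar channels, in nats.

    I = ψ(k) + ψ(N) − mean[ψ(n_x + 1) + ψ(n_y + 1)] where n_x, n_y
    count marginal neighbors strictly inside the max-norm distance to
    the k-th joint neighbor.  The raw estimate is returned; it can dip
    slightly below 0 — clamp at 0 when a non-negative value is needed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("ksg_mi expects two equal-length channels")
    n = len(x)
    if spec.k >= n:
        raise DataError(f"k={spec.k} must be smaller than N={n}")
    rng = np.random.default_rng(seed)
    x = _jitter(x, rng)
    y = _jitter(y, rng)
    z = np.column_stack([x, y])
    tree = cKDTree(z)
    dist, _ = tree.query(z, k=spec.k + 1, p=np.inf)
    eps = dist[:, -1]
    nx = _strict_marginal_counts(x, eps)
    ny = _strict_marginal_counts(y, eps)
    return float(
        digamma(spec.k) + digamma(n)
        - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def _strict_marginal_counts(x: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """#{j != i : |x_j − x_i| < eps_i} via a sorted marginal."""
    order = np.argsort(x)
    xs = x[order]
    lo = np.searchsorted(xs, x - eps, side="right")
    hi = np.searchsorted(xs, x + eps, side="left")
    return np.maximum(hi - lo - 1, 0)


def kl_entropy(x: np.ndarray, spec: EstimatorSpec = EstimatorSpec(),
               seed: int = 0) -> float:
    """Kozachenko–Leonenko differential entropy of a channel, in nats.

    H = ψ(N) − ψ(k) + d·mean[ln(2 ε_i)] with ε_i the max-norm distance
    to the k-th neighbor (d = 1 for a scalar channel; 2^d is the
    max-norm unit-ball volume).
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if spec.k >= n:
        raise DataError(f"k={spec.k} must be smaller than N={n}")
    rng = np.random.default_rng(seed)
    x = _jitter(x, rng)
    tree = cKDTree(x)
    dist, _ = tree.query(x, k=spec.k + 1, p=np.inf)
    eps = dist[:, -1]
    if np.any(eps <= 0.0):
        raise DataError("zero nearest-neighbor distances persist after jitter")
    return float(digamma(n) - digamma(spec.k) + d * np.mean(np.log(2.0 * eps)))


def correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient in [−1, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise DataError("channels must have equal length")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DataError("constant channel; correlation undefined")
    return float(pearsonr(x, y)[0])
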