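"""Convergent cross sorting (CCS) and the exponential-weight convergent
cross mapping (CCM) reconstruction it extends.

Direction convention (cross-map): the score for "x causes y" asks how
well the *effect's* reconstructed geometry recovers the *cause*.  If x
drives y, the delay embedding of y embeds the joint dynamics, so pairs
of states that are close in the y-reconstruction must also be close in
the x-reconstruction.

CCS makes this comparison dimensionless: pairwise distances in each
reconstruction are replaced by evenly spaced ranks in [0, 1]; the
normalized sorting error

    E(R) = mean |R_x − R_y| over pairs with R_y <= R, divided by 1/3

is 1 for unrelated series (1/3 is the mean |U − V| of independent
uniforms, the random-sorting expectation) and drops toward 0 at small R
under coupling.  E(R) is fitted by a + b·e^{cR}; the causality score is
max(0, 1 − E(0)) with E(0) = a + b, so independent series score ≈ 0 and
strong coupling saturates at 1.  Being rank-based, the score is exactly
invariant under positive affine transforms of either series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, pearsonr

from .embedding import DelayEmbedding, EmbeddingParams, delay_embed, nearest_neighbors
from .errors import DataError

__all__ = ["CCMResult", "RankCurve", "ccm_cross_map", "rank_transform",
           "ccs_score", "PreparedCCS"]

RANDOM_SORT_ERROR = 1.0 / 3.0  # E|U − V| for independent uniforms on [0,1]


@dataclass
class CCMResult:
    rho: float
    weights_stat: dict
    params: EmbeddingParams


@dataclass
class RankCurve:
    """Normalized sorting-error curve and its exponential fit.

    ``e0 = fit_a + fit_b`` is the fitted error at rank 0; the causality
    score is ``max(0, 1 − e0)``.  ``fallback`` marks results where the
    exponential fit failed and e0 came from linear extrapolation of the
    two smallest-R error values.
    """

    r_values: np.ndarray
    e_values: np.ndarray
    fit_a: float
    fit_b: float
    fit_c: float
    e0: float
    fallback: bool = False

    @property
    def score(self) -> float:
        return max(0.0, 1.0 - self.e0)


def ccm_cross_map(
    source_embedding: DelayEmbedding, target: np.ndarray, theiler: int = 0
) -> CCMResult:
    """CCM reconstruction of ``target`` from the geometry of
    ``source_embedding``.

    ``target`` must be aligned with the embedding's rows (one value per
    point).  For each point the dim+1 nearest neighbors supply
    exponential weights e^{−d_i/d_1}, normalized to sum 1; the target is
    reconstructed as the weighted neighbor average and the result is the
    Pearson correlation between target and reconstruction.  A zero
    nearest-neighbor distance degenerates the weights to uniform over
    the zero-distance set.
    """
    target = np.asarray(target, float)
    if len(target) != source_embedding.n_points:
        raise DataError("target must be aligned with the embedding rows")
    if np.std(target) == 0.0:
        raise DataError("constant target; correlation undefined")
    k = source_embedding.params.dim + 1
    if source_embedding.n_points < k + 1:
        raise DataError(f"need at least dim+2={k + 1} points")
    idx, dist = nearest_neighbors(source_embedding, k, theiler=theiler)
    d1 = dist[:, 0:1]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.exp(-dist / d1)
    zero_rows = (d1[:, 0] == 0.0)
    if zero_rows.any():
        w[zero_rows] = (dist[zero_rows] == 0.0).astype(float)
    w /= w.sum(axis=1, keepdims=True)
    recon = (w * target[idx]).sum(axis=1)
    rho = float(pearsonr(target, recon)[0])
    stats = {"k": k, "mean_top_weight": float(w[:, 0].mean())}
    return CCMResult(rho, stats, source_embedding.params)


def rank_transform(distances: np.ndarray) -> np.ndarray:
    """Replace values by evenly spaced ranks in [0, 1], ties sharing the
    mean of their would-be ranks, returned in the input order."""
    d = np.asarray(distances, float)
    if d.size < 2:
        raise DataError("rank transform needs at least 2 values")
    return (rankdata(d, method="average") - 1.0) / (d.size - 1.0)


def _sample_pairs(n: int, n_pairs: int, rng: np.random.Generator,
                  times: np.ndarray, theiler: int):
    """Sample up to n_pairs distinct index pairs i<j, excluding pairs
    closer in time than the Theiler window."""
    total = n * (n - 1) // 2
    if total <= n_pairs:
        i, j = np.triu_indices(n, k=1)
    else:
        # sample linear indices of the strict upper triangle
        take = min(n_pairs, total)
        lin = rng.choice(total, size=take, replace=False)
        # invert the triangular numbering row by row
        i = (n - 2 - np.floor(
            np.sqrt(-8.0 * lin + 4.0 * n * (n - 1) - 7) / 2.0 - 0.5
        )).astype(np.int64)
        j = (lin + i + 1 - i * (2 * n - i - 1) // 2).astype(np.int64)
    if theiler > 0:
        keep = np.abs(times[i] - times[j]) > theiler
        i, j = i[keep], j[keep]
    if i.size < 2:
        raise DataError("too few point pairs after Theiler exclusion")
    return i, j


def _fit_exponential(r: np.ndarray, e: np.ndarray):
    """Bounded nonlinear least squares of e ≈ a + b·exp(c·r) by variable
    projection: closed-form (a, b) on a grid of decay rates c, bounds
    a∈[0,2], b∈[−2,2], c<0."""
    c_grid = -np.geomspace(0.05, 50.0, 64)
    g = np.exp(np.outer(c_grid, r))          # (n_c, n_r)
    m = float(len(r))
    sx = g.sum(axis=1)
    sxx = (g * g).sum(axis=1)
    sy = float(e.sum())
    sxy = g @ e
    denom = m * sxx - sx * sx
    valid = denom > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (m * sxy - sx * sy) / denom
        a = (sy - b * sx) / m
    a = np.clip(a, 0.0, 2.0)
    b = np.clip(b, -2.0, 2.0)
    resid = a[:, None] + b[:, None] * g - e[None, :]
    sse = (resid * resid).sum(axis=1)
    sse[~valid] = np.inf
    if not np.isfinite(sse).any():
        return None
    k = int(np.argmin(sse))
    return float(a[k]), float(b[k]), float(c_grid[k])


class PreparedCCS:
    """CCS scorer with the effect-side geometry precomputed.

    The effect reconstruction, the sampled point pairs, their
    effect-space ranks and the pair ordering stay fixed; only the cause
    series varies across calls.  This is what makes surrogate testing
    cheap: ``score(cause)`` recomputes just the cause-space ranks and
    the curve fit.
    """

    def __init__(
        self,
        effect: np.ndarray,
        params_cause: EmbeddingParams,
        params_effect: EmbeddingParams,
        n_pairs: int = 20000,
        n_levels: int = 20,
        seed: int = 0,
        theiler: int = 0,
    ):
        effect = np.asarray(effect, float)
        self.params_cause = params_cause
        self.params_effect = params_effect
        self.L = len(effect)
        self.t0 = max(params_cause.window, params_effect.window)
        emb_y = delay_embed(effect, params_effect)
        # rows of the effect embedding at the aligned times t0..L-1
        y_pts = emb_y.points[self.t0 - params_effect.window :]
        n = y_pts.shape[0]
        if n < 8:
            raise DataError("series too short for CCS after alignment")
        rng = np.random.default_rng(seed)
        times = np.arange(self.t0, self.L)
        self._i, self._j = _sample_pairs(n, n_pairs, rng, times, theiler)
        dy2 = ((y_pts[self._i] - y_pts[self._j]) ** 2).sum(axis=1)
        self._ry = rank_transform(dy2)
        self._order = np.argsort(dy2, kind="stable")
        m = self._i.size
        self.r_values = np.arange(1, n_levels + 1) / n_levels
        self._level_counts = np.maximum(
            1, np.round(self.r_values * m).astype(int)
        )

    def score(self, cause: np.ndarray) -> RankCurve:
        cause = np.asarray(cause, float)
        if len(cause) != self.L:
            raise DataError("cause and effect series must have equal length")
        emb_x = delay_embed(cause, self.params_cause)
        x_pts = emb_x.points[self.t0 - self.params_cause.window :]
        dx2 = ((x_pts[self._i] - x_pts[self._j]) ** 2).sum(axis=1)
        rx = rank_transform(dx2)
        disc = np.abs(rx - self._ry)[self._order]
        cum = np.cumsum(disc)
        counts = self._level_counts
        e = cum[counts - 1] / counts / RANDOM_SORT_ERROR
        fit = _fit_exponential(self.r_values, e)
        if fit is None or not all(np.isfinite(fit)):
            # linear extrapolation of the two smallest-R errors
            r0, r1 = self.r_values[:2]
            e0 = float(e[0] - (e[1] - e[0]) / (r1 - r0) * r0)
            return RankCurve(self.r_values, e, np.nan, np.nan, np.nan,
                             e0, fallback=True)
        a, b, c = fit
        return RankCurve(self.r_values, e, a, b, c, a + b)


def ccs_score(
    x: np.ndarray,
    y: np.ndarray,
    params_x: EmbeddingParams | None = None,
    params_y: EmbeddingParams | None = None,
    n_pairs: int = 20000,
    n_levels: int = 20,
    seed: int = 0,
    theiler: int = 0,
) -> RankCurve:
    """CCS causality score for "x causes y" (cross-map convention).

    Embedding parameters default to (dim=2, lag=1), the map benchmark
    setting; pass explicit parameters for flows.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise DataError("x and y must have equal length")
    params_x = params_x or EmbeddingParams(2, 1)
    params_y = params_y or EmbeddingParams(2, 1)
    prepared = PreparedCCS(y, params_x, params_y, n_pairs=n_pairs,
                           n_levels=n_levels, seed=seed, theiler=theiler)
    return prepared.score(x)
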