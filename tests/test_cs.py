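"""Continuity scaling: the ε grid, the δ(ε) curve and the directional
strength."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from crosscause import (
    DataError,
    EmbeddingParams,
    LogisticParams,
    cs_strength,
    delay_embed,
    eps_grid,
    simulate_logistic_pair,
)


class TestEpsGrid:
    def test_endpoints_are_percentiles(self, rng):
        pts = rng.normal(size=(300, 2))
        emb = delay_embed(rng.normal(size=301), EmbeddingParams(2, 1))
        emb.points = pts
        grid = eps_grid(emb, n_eps=2, seed=0)
        i, j = np.triu_indices(300, k=1)
        d = np.sqrt(((pts[i] - pts[j]) ** 2).sum(1))
        np.testing.assert_allclose(grid, np.percentile(d, [1, 50]), rtol=1e-12)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(200, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = eps_grid(pts, n_eps=8, seed=1)
        b = eps_grid(pts @ R.T, n_eps=8, seed=1)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_homogeneous_scaling(self, rng):
        pts = rng.normal(size=(200, 3))
        a = eps_grid(pts, n_eps=6, seed=2)
        b = eps_grid(10.0 * pts, n_eps=6, seed=2)
        np.testing.assert_allclose(b, 10.0 * a, rtol=1e-9)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(DataError):
            eps_grid(np.zeros((100, 2)), n_eps=5)

    def test_strictly_increasing(self, rng):
        grid = eps_grid(rng.normal(size=(300, 2)), n_eps=12)
        assert (np.diff(grid) > 0).all()


class TestCSStrength:
    def test_null_slope_small_relative_to_coupled(self):
        # per-run sd is ~0.016, so 300 runs put the mean's sampling
        # error well below the 5%-of-coupled-scale threshold
        rng = np.random.default_rng(3)
        null = [
            cs_strength(rng.normal(size=400), rng.normal(size=400), seed=s).slope
            for s in range(300)
        ]
        coupled = []
        for s in range(30):
            ts = simulate_logistic_pair(
                LogisticParams(C1=0.0, C2=0.1, L=400, seed=s)
            )
            coupled.append(
                cs_strength(ts.channel("x1"), ts.channel("x2"), seed=s).slope
            )
        assert abs(np.mean(null)) < 0.05 * np.mean(coupled)

    def test_homeomorphic_pair_bidirectional(self):
        # y = x^3 is smooth and invertible: continuity holds both ways
        ts = simulate_logistic_pair(LogisticParams(L=400, seed=1))
        x = ts.channel("x1")
        y = x**3
        assert cs_strength(x, y, seed=0).slope > 0.02
        assert cs_strength(y, x, seed=0).slope > 0.02

    def test_direction_on_coupled_pair(self):
        wins = 0
        for seed in range(100):
            ts = simulate_logistic_pair(
                LogisticParams(C1=0.0, C2=0.1, L=400, seed=seed)
            )
            x1, x2 = ts.channel("x1"), ts.channel("x2")
            fwd = cs_strength(x1, x2, seed=seed).slope
            rev = cs_strength(x2, x1, seed=seed).slope
            wins += fwd > rev
        assert wins >= 95

    def test_delta_monotone_in_eps(self):
        # ball containment makes the containing-radius ('max') curve
        # exactly non-decreasing; the default mean-member radius shares
        # the shape through the scaling region, with at most tiny
        # sampling dips after saturation
        for seed in range(10):
            ts = simulate_logistic_pair(
                LogisticParams(C1=0.0, C2=0.1, L=400, seed=seed)
            )
            x1, x2 = ts.channel("x1"), ts.channel("x2")
            strict = cs_strength(x1, x2, seed=seed, radius_stat="max")
            assert (np.diff(strict.delta_values) >= -1e-12).all()
            res = cs_strength(x1, x2, seed=seed)
            span = res.delta_values.max() - res.delta_values.min()
            diffs = np.diff(res.delta_values)
            # strictly rising through the scaling region; only small
            # rollover dips after saturation
            assert (diffs[: len(diffs) * 2 // 3] > 0).all()
            assert (diffs >= -0.1 * span).all()

    def test_affine_invariance(self, coupled_logistic):
        # ranks are exact; standardization leaves float-rounding noise
        x1, x2 = coupled_logistic
        a = cs_strength(x1, x2, seed=5)
        b = cs_strength(3.0 * x1 + 1.0, x2, seed=5)
        c = cs_strength(x1, 0.5 * x2 - 4.0, seed=5)
        np.testing.assert_allclose(a.slope, b.slope, rtol=1e-9)
        np.testing.assert_allclose(a.slope, c.slope, rtol=1e-9)

    def test_monotone_in_coupling(self):
        # mirrors the progressive increase of detected strength with C2
        levels = [0.0, 0.05, 0.1, 0.2, 0.4]
        means = []
        for C2 in levels:
            vals = []
            for seed in range(100):
                ts = simulate_logistic_pair(
                    LogisticParams(C1=0.0, C2=C2, L=400, seed=seed)
                )
                vals.append(
                    cs_strength(ts.channel("x1"), ts.channel("x2"),
                                seed=seed).slope
                )
            means.append(np.mean(vals))
        rho, _ = spearmanr(levels, means)
        assert rho > 0

    def test_reproducible(self, coupled_logistic):
        x1, x2 = coupled_logistic
        a = cs_strength(x1, x2, seed=11)
        b = cs_strength(x1, x2, seed=11)
        assert a.slope == b.slope
        np.testing.assert_array_equal(a.delta_values, b.delta_values)

    def test_result_contract(self, coupled_logistic):
        x1, x2 = coupled_logistic
        res = cs_strength(x1, x2, seed=0)
        assert (np.diff(res.eps_grid) > 0).all() and (res.eps_grid > 0).all()
        assert (res.delta_values >= 0).all()
        assert np.isfinite(res.slope)
        assert 0.0 <= res.fit_r2 <= 1.0

    def test_n_ref_precondition(self, coupled_logistic):
        x1, x2 = coupled_logistic
        with pytest.raises(DataError):
            cs_strength(x1, x2, n_ref=5)
        with pytest.raises(DataError):
            cs_strength(x1, x2, n_eps=3)
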