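"""Simulator correctness: map updates, vector fields, decoupling,
divergence handling, noise calibration and standardization."""

import numpy as np
import pytest

from crosscause import (
    DataError,
    LogisticParams,
    NetworkSpec,
    NoiseSpec,
    RosslerLorenzParams,
    RosslerRosslerParams,
    add_noise,
    logistic_step,
    rossler_lorenz_field,
    rossler_rossler_field,
    simulate_logistic_network,
    simulate_logistic_pair,
    simulate_rossler_lorenz,
    simulate_rossler_rossler,
    standardize,
)
from crosscause.simulate import _integrate_batch
from crosscause.timeseries import TimeSeriesSet


def _pair_matrix(C1, C2):
    return np.array([[0.0, C1], [C2, 0.0]])


class TestLogisticPair:
    def test_single_step_update(self):
        # x1' = 0.2 * (3.6 - 3.6*0.2 - 0.1*0.5) = 0.566
        new = logistic_step(np.array([0.2, 0.5]), np.array([3.6, 3.7]),
                            _pair_matrix(0.1, 0.0))
        assert new[0] == pytest.approx(0.2 * (3.6 - 0.72 - 0.05), abs=1e-15)

    def test_uncoupled_fixed_point(self):
        # r=2 logistic map has fixed point 0.5
        state = np.array([0.5, 0.5])
        r = np.array([2.0, 2.0])
        for _ in range(50):
            state = logistic_step(state, r, _pair_matrix(0.0, 0.0))
        assert state == pytest.approx([0.5, 0.5])

    def test_time_average_matches_recursion_oracle(self):
        params = LogisticParams(r1=3.6, C1=0.0, C2=0.0, L=10_000, seed=5)
        ts = simulate_logistic_pair(params)
        # independent scalar re-implementation of the recursion from the
        # recorded initial state
        x = float(ts.meta["initial_state"][0])
        acc, burn = [], params.transient
        for t in range(burn + params.L):
            x = x * (3.6 - 3.6 * x)
            if t >= burn:
                acc.append(x)
        assert np.mean(ts.channel("x1")) == pytest.approx(np.mean(acc), abs=1e-3)
        np.testing.assert_allclose(ts.channel("x1"), acc, atol=1e-12)

    def test_reproducible_bit_exact(self):
        p = LogisticParams(C1=0.3, C2=0.7, L=300, seed=9)
        a = simulate_logistic_pair(p).values
        b = simulate_logistic_pair(p).values
        np.testing.assert_array_equal(a, b)

    def test_trajectories_stay_in_unit_interval(self):
        for seed in range(5):
            ts = simulate_logistic_pair(
                LogisticParams(C1=1.0, C2=1.0, L=400, seed=seed)
            )
            assert ts.values.min() >= 0.0 and ts.values.max() <= 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(Exception):
            simulate_logistic_pair(LogisticParams(L=0))


class TestLogisticNetwork:
    def test_ring_every_node_has_one_parent(self):
        A = NetworkSpec(topology="ring").adjacency()
        assert ((A > 0).sum(axis=1) == 1).all()

    def test_chain_edge_count(self):
        A = NetworkSpec(topology="chain", n_nodes=20).adjacency()
        assert (A > 0).sum() == 19

    def test_zero_coupling_factorizes_to_scalar_maps(self):
        spec = NetworkSpec(topology="chain", n_nodes=5, coupling=0.0)
        ts = simulate_logistic_network(spec, L=200, seed=3, transient=100)
        for i in range(5):
            x = float(ts.meta["initial_state"][i])
            r = spec.node_growth_rates[i]
            out = []
            for t in range(100 + 200):
                x = x * (r - r * x)
                if t >= 100:
                    out.append(x)
            np.testing.assert_allclose(ts.values[:, i], out, atol=1e-12)

    def test_chain_head_node_independent_of_downstream(self):
        # node 1 has no parents in the chain: its series must equal the
        # scalar recursion from its own recorded initial value alone
        spec = NetworkSpec(topology="chain", n_nodes=4, coupling=0.25)
        ts = simulate_logistic_network(spec, L=150, seed=8, transient=50)
        x = float(ts.meta["initial_state"][0])
        r = spec.node_growth_rates[0]
        out = []
        for t in range(50 + 150):
            x = x * (r - r * x)
            if t >= 50:
                out.append(x)
        np.testing.assert_allclose(ts.values[:, 0], out, atol=1e-12)


class TestFlows:
    def test_rossler_lorenz_field_values(self):
        state = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        d = rossler_lorenz_field(state, a=6.0, C=0.0)
        assert d[0] == pytest.approx(-12.0)          # -a(x2+x3)
        state2 = np.array([0.0, 2.0, 0.0, 1.0, 1.0, 1.0])
        d2 = rossler_lorenz_field(state2, a=6.0, C=0.1)
        assert d2[4] == pytest.approx(28 - 1 - 1 + 0.1 * 4)  # 26.4

    def test_rossler_rossler_field_values(self):
        p = RosslerRosslerParams(omega1=1.0, omega2=1.0, C=0.5)
        state = np.array([2.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        d = rossler_rossler_field(state, p)
        assert d[3] == pytest.approx(-1.0 - 1.0 + 0.5 * (2.0 - 1.0))  # -1.5

    def test_response_decoupled_at_zero_coupling(self):
        # with C=0 the Lorenz trajectory cannot depend on the Rössler
        # parameters: same seed, different a, bit-identical y channels
        ya = simulate_rossler_lorenz(
            RosslerLorenzParams(a=6.0, C=0.0, L=50, transient_time=20, seed=2)
        ).values[:, 3:]
        yb = simulate_rossler_lorenz(
            RosslerLorenzParams(a=10.0, C=0.0, L=50, transient_time=20, seed=2)
        ).values[:, 3:]
        np.testing.assert_array_equal(ya, yb)

    def test_identical_twin_rossler_at_zero_coupling(self):
        # C=0, omega1=omega2, identical initial conditions for both
        # subsystems: x and y trajectories coincide exactly
        p = RosslerRosslerParams(omega1=1.0, omega2=1.0, C=0.0)
        y0 = np.array([[1.0, 2.0, 0.5, 1.0, 2.0, 0.5]])
        traj, ok = _integrate_batch(
            lambda y: rossler_rossler_field(y, p), y0, p.dt, 60, 100, 0
        )
        assert ok.all()
        np.testing.assert_array_equal(traj[0][:, :3], traj[0][:, 3:])

    def test_rk4_step_halving_converges(self):
        # short pre-chaotic horizon (~5 time units); chaos precludes
        # trajectory comparison over long horizons
        y0 = np.array([[1.0, 2.0, 0.5, 5.0, -3.0, 20.0]])
        f = lambda y: rossler_lorenz_field(y, 6.0, 2.0)
        a, _ = _integrate_batch(f, y0, 0.005, 60, 17, 0)
        b, _ = _integrate_batch(f, y0, 0.0025, 120, 17, 0)
        assert np.sqrt(np.mean((a - b) ** 2)) < 1e-4

    def test_dominant_frequency_tracks_omega(self):
        from scipy.signal import periodogram

        p = RosslerRosslerParams(omega1=1.0, omega2=1.0, C=0.0, L=4096, seed=3)
        ts = simulate_rossler_rossler(p)
        f, P = periodogram(ts.channel("x1"), fs=1.0 / p.sample_every)
        peak = f[np.argmax(P)]
        # the chaotic Rössler peak sits slightly above omega/(2*pi)
        assert abs(peak - 1.0 / (2 * np.pi)) < 0.01

    def test_reproducible_bit_exact(self):
        p = RosslerLorenzParams(L=30, transient_time=10, seed=4)
        np.testing.assert_array_equal(
            simulate_rossler_lorenz(p).values, simulate_rossler_lorenz(p).values
        )

    def test_sample_every_must_be_multiple_of_dt(self):
        with pytest.raises(Exception):
            simulate_rossler_lorenz(RosslerLorenzParams(dt=0.007, sample_every=0.3))


class TestNoise:
    def test_zero_db_noise_variance_matches_signal(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(100_000, 1)), ["a"])
        noisy = add_noise(ts, NoiseSpec(snr_db=0.0, seed=1))
        ratio = np.var(noisy.values - ts.values) / np.var(ts.values)
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_twenty_db_noise_sd(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(50_000, 1)), ["a"])
        noisy = add_noise(ts, NoiseSpec(snr_db=20.0, seed=1))
        sd = np.std(noisy.values - ts.values)
        assert sd == pytest.approx(0.1 * np.std(ts.values), rel=0.05)

    def test_vanishing_noise_limit(self, rng):
        ts = TimeSeriesSet(rng.uniform(1, 2, size=(1000, 2)), ["a", "b"])
        noisy = add_noise(ts, NoiseSpec(snr_db=300.0, seed=1))
        np.testing.assert_allclose(noisy.values, ts.values, rtol=1e-10)

    def test_empirical_snr_within_half_db(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(10_000, 1)), ["a"])
        for target in (5.0, 15.0, 30.0):
            noisy = add_noise(ts, NoiseSpec(snr_db=target, seed=7))
            emp = 10 * np.log10(
                np.var(ts.values) / np.var(noisy.values - ts.values)
            )
            assert abs(emp - target) < 0.5

    def test_constant_channel_rejected(self):
        ts = TimeSeriesSet(np.ones((100, 1)), ["a"])
        with pytest.raises(DataError):
            add_noise(ts, NoiseSpec(snr_db=10.0))

    def test_original_untouched(self, rng):
        values = rng.normal(size=(500, 1))
        ts = TimeSeriesSet(values.copy(), ["a"])
        add_noise(ts, NoiseSpec(snr_db=5.0, seed=0))
        np.testing.assert_array_equal(ts.values, values)


class TestStandardize:
    def test_three_point_example(self):
        ts = TimeSeriesSet(np.array([[1.0], [2.0], [3.0]]), ["a"])
        np.testing.assert_allclose(
            standardize(ts).values[:, 0], [-1.0, 0.0, 1.0]
        )

    def test_idempotent(self, rng):
        ts = TimeSeriesSet(rng.normal(3, 5, size=(400, 2)), ["a", "b"])
        once = standardize(ts)
        twice = standardize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(300, 1))
        a = standardize(TimeSeriesSet(x, ["a"])).values
        b = standardize(TimeSeriesSet(4.2 * x + 7.0, ["a"])).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_channel_rejected(self):
        with pytest.raises(DataError):
            standardize(TimeSeriesSet(np.full((50, 1), 3.0), ["flat"]))
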