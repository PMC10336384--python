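"""Synthetic benchmark systems: coupled logistic maps (pairs and 20-node
networks), the Rössler–Lorenz system, the Rössler–Rössler system, additive
Gaussian measurement noise, and channel standardization.

Conventions
-----------
* All simulators are deterministic given their ``seed``; initial
  conditions are drawn from the seeded generator and recorded in
  ``meta`` so a run can be regenerated bit-exactly.
* Logistic maps iterate x_i(t+1) = x_i(t)[r_i − r_i x_i(t) − Σ_j A_ij x_j(t)]
  where A_ij is the coupling of node j into node i.  Trajectories must
  stay in [0, 1]; a trajectory that leaves the unit interval (possible
  at strong coupling) is rejected and its initial condition resampled,
  up to ``MAX_RESAMPLES`` attempts, with the resample count reported in
  ``meta``.
* Flows are integrated with fixed-step classical RK4 (dt = 0.005 by
  default), a burn-in of ``transient_time`` time units is discarded and
  the state is then recorded every ``sample_every`` time units.
* Measurement noise is added after simulation (never fed back into the
  dynamics) with per-channel standard deviation
  sigma_noise = sigma_signal * 10**(−snr_db/20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, DataError, SimulationError
from .timeseries import TimeSeriesSet

MAX_RESAMPLES = 20

__all__ = [
    "LogisticParams",
    "NetworkSpec",
    "RosslerLorenzParams",
    "RosslerRosslerParams",
    "NoiseSpec",
    "logistic_step",
    "simulate_logistic_pair",
    "simulate_logistic_network",
    "rossler_lorenz_field",
    "rossler_rossler_field",
    "simulate_rossler_lorenz",
    "simulate_rossler_rossler",
    "rossler_lorenz_ensemble",
    "rossler_rossler_ensemble",
    "add_noise",
    "standardize",
]


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class LogisticParams:
    """Bidirectionally coupled logistic map pair.

    C1 couples x2 into x1's equation; C2 couples x1 into x2's.  The
    benchmark growth rates are r1 = 3.6 and r2 = 3.7.
    """

    r1: float = 3.6
    r2: float = 3.7
    C1: float = 0.0
    C2: float = 0.0
    L: int = 400
    transient: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.L <= 0:
            raise ConfigError("L must be positive")
        if self.transient < 0:
            raise ConfigError("transient must be >= 0")
        if self.C1 < 0 or self.C2 < 0:
            raise ConfigError("couplings must be >= 0")


@dataclass
class NetworkSpec:
    """Chain or ring of unidirectionally coupled logistic maps.

    Node growth rates default to 20 values uniformly spaced on
    [3.6, 3.8]; each directed edge carries the same scalar coupling.
    A chain has n−1 edges (node i drives node i+1); a ring closes the
    loop with an edge from the last node back to the first.
    """

    topology: str = "chain"
    n_nodes: int = 20
    node_growth_rates: np.ndarray | None = None
    coupling: float = 0.1

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "ring"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.n_nodes < 2:
            raise ConfigError("need at least 2 nodes")
        if self.node_growth_rates is None:
            self.node_growth_rates = np.linspace(3.6, 3.8, self.n_nodes)
        self.node_growth_rates = np.asarray(self.node_growth_rates, float)
        if self.node_growth_rates.shape != (self.n_nodes,):
            raise ConfigError("node_growth_rates must have one entry per node")

    def adjacency(self) -> np.ndarray:
        """Coupling matrix A with A[i, j] = coupling of node j into node i."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for i in range(self.n_nodes - 1):
            A[i + 1, i] = self.coupling
        if self.topology == "ring":
            A[0, self.n_nodes - 1] = self.coupling
        return A


@dataclass
class RosslerLorenzParams:
    """Rössler (time-scaled by ``a``) unidirectionally driving a Lorenz
    system through the quadratic term C·x2² in the dy2/dt equation."""

    a: float = 6.0
    C: float = 2.0
    dt: float = 0.005
    sample_every: float = 0.3
    transient_time: float = 500.0
    L: int = 400
    seed: int = 0

    def validate(self) -> None:
        _validate_flow(self)


@dataclass
class RosslerRosslerParams:
    """Two Rössler oscillators with angular frequencies omega1 (driver)
    and omega2 (response), diffusively coupled x1 → y1 with strength C.

    The frequency ratio r = omega1/omega2 is derived, never stored.  The
    response's third equation is implemented in the standard Rössler
    form dy3/dt = y3(y1 − c) + b2 by default; ``y3_sign='plus'`` flips
    the sign of c for the non-standard variant.
    """

    omega1: float = 1.0
    omega2: float = 1.0
    a1: float = 0.15
    a2: float = 0.15
    b1: float = 0.2
    b2: float = 0.2
    c: float = 10.0
    C: float = 0.1
    dt: float = 0.005
    sample_every: float = 0.3
    transient_time: float = 500.0
    L: int = 400
    seed: int = 0
    y3_sign: str = "minus"

    @property
    def frequency_ratio(self) -> float:
        return self.omega1 / self.omega2

    def validate(self) -> None:
        if self.omega1 <= 0 or self.omega2 <= 0:
            raise ConfigError("omega1 and omega2 must be positive")
        if self.y3_sign not in ("minus", "plus"):
            raise ConfigError("y3_sign must be 'minus' or 'plus'")
        _validate_flow(self)


def _validate_flow(p) -> None:
    if p.dt <= 0:
        raise ConfigError("dt must be positive")
    if p.sample_every < p.dt:
        raise ConfigError("sample_every must be >= dt")
    stride = p.sample_every / p.dt
    if abs(stride - round(stride)) > 1e-9:
        raise ConfigError("sample_every must be an integer multiple of dt")
    if p.L <= 0:
        raise ConfigError("L must be positive")
    if p.transient_time < 0:
        raise ConfigError("transient_time must be >= 0")


@dataclass
class NoiseSpec:
    """Additive zero-mean Gaussian white measurement noise at a given
    signal-to-noise ratio in decibels (independent across time and
    across channels)."""

    snr_db: float
    seed: int = 0


# ---------------------------------------------------------------------------
# logistic maps
# ---------------------------------------------------------------------------

def logistic_step(state: np.ndarray, r: np.ndarray, A: np.ndarray) -> np.ndarray:
    """One update of the coupled-map lattice.

    ``state`` is (..., n_nodes); ``r`` the per-node growth rates;
    ``A[i, j]`` the coupling of node j into node i's equation.
    """
    state = np.asarray(state, float)
    coupling = state @ A.T
    return state * (r - r * state - coupling)


def _logistic_batch(
    r: np.ndarray,
    A: np.ndarray,
    L: int,
    transient: int,
    n_reps: int,
    seed: int,
):
    """Iterate ``n_reps`` independent realizations, resampling initial
    conditions for any realization that leaves [0, 1] or turns
    non-finite.  Returns (trajectories (n_reps, L, n), initial states,
    resample count)."""
    rng = np.random.default_rng(seed)
    n = len(r)
    out = np.empty((n_reps, L, n))
    init = rng.uniform(0.05, 0.95, size=(n_reps, n))
    initial_used = init.copy()
    pending = np.arange(n_reps)
    resamples = 0
    for attempt in range(MAX_RESAMPLES + 1):
        traj, ok = _run_logistic(init[pending], r, A, L, transient)
        good = pending[ok]
        out[good] = traj[ok]
        initial_used[good] = init[good]
        pending = pending[~ok]
        if pending.size == 0:
            break
        if attempt == MAX_RESAMPLES:
            raise SimulationError(
                f"logistic trajectory left [0,1] after {MAX_RESAMPLES} "
                f"resamples (r={r.tolist()}, couplings={A.tolist()})"
            )
        resamples += pending.size
        init[pending] = rng.uniform(0.05, 0.95, size=(pending.size, n))
    return out, initial_used, resamples


def _run_logistic(state0, r, A, L, transient):
    state = state0.copy()
    ok = np.ones(state.shape[0], dtype=bool)
    traj = np.empty((state.shape[0], L, state.shape[1]))
    for t in range(transient + L):
        state = logistic_step(state, r, A)
        bad = ~(np.isfinite(state).all(axis=1) & (state >= 0).all(axis=1)
                & (state <= 1).all(axis=1))
        if bad.any():
            ok &= ~bad
            state[bad] = 0.5  # park rejected rows to avoid overflow
        if t >= transient:
            traj[:, t - transient] = state
    return traj, ok


def simulate_logistic_pair(params: LogisticParams) -> TimeSeriesSet:
    """Simulate the bidirectionally coupled logistic pair.

    Returns a 2-channel set (x1, x2) of length ``L`` after discarding
    ``transient`` steps.  Initial conditions ~ U(0.05, 0.95).
    """
    params.validate()
    r = np.array([params.r1, params.r2])
    A = np.array([[0.0, params.C1], [params.C2, 0.0]])
    traj, init, resamples = _logistic_batch(
        r, A, params.L, params.transient, 1, params.seed
    )
    meta = {
        "system": "logistic_pair",
        "params": asdict(params),
        "initial_state": init[0],
        "resamples": resamples,
    }
    return TimeSeriesSet(traj[0], ["x1", "x2"], dt=1.0, meta=meta)


def simulate_logistic_network(
    spec: NetworkSpec, L: int = 400, seed: int = 0, transient: int = 1000
) -> TimeSeriesSet:
    """Simulate a chain or ring of coupled logistic maps (one channel
    per node, named ``x1`` ... ``xn``)."""
    if L <= 0:
        raise ConfigError("L must be positive")
    traj, init, resamples = _logistic_batch(
        spec.node_growth_rates, spec.adjacency(), L, transient, 1, seed
    )
    meta = {
        "system": f"logistic_{spec.topology}",
        "params": {
            "topology": spec.topology,
            "n_nodes": spec.n_nodes,
            "node_growth_rates": spec.node_growth_rates,
            "coupling": spec.coupling,
            "L": L,
            "transient": transient,
            "seed": seed,
        },
        "initial_state": init[0],
        "resamples": resamples,
    }
    names = [f"x{i+1}" for i in range(spec.n_nodes)]
    return TimeSeriesSet(traj[0], names, dt=1.0, meta=meta)


# ---------------------------------------------------------------------------
# flows
# ---------------------------------------------------------------------------

def rossler_lorenz_field(state: np.ndarray, a: float, C: float) -> np.ndarray:
    """Vector field of the coupled Rössler–Lorenz system.

    ``state`` is (..., 6) ordered (x1, x2, x3, y1, y2, y3).
    """
    x1, x2, x3, y1, y2, y3 = np.moveaxis(np.asarray(state, float), -1, 0)
    return np.stack(
        [
            -a * (x2 + x3),
            a * (x1 + 0.2 * x2),
            a * (0.2 + x3 * (x1 - 5.7)),
            10.0 * (y2 - y1),
            28.0 * y1 - y2 - y1 * y3 + C * x2**2,
            y1 * y2 - (8.0 / 3.0) * y3,
        ],
        axis=-1,
    )


def rossler_rossler_field(state: np.ndarray, p: RosslerRosslerParams) -> np.ndarray:
    """Vector field of the coupled Rössler–Rössler system; the coupling
    C(x1 − y1) acts only in the dy1/dt equation."""
    x1, x2, x3, y1, y2, y3 = np.moveaxis(np.asarray(state, float), -1, 0)
    c_resp = -p.c if p.y3_sign == "minus" else p.c
    return np.stack(
        [
            -p.omega1 * x2 - x3,
            p.omega1 * x1 + p.a1 * x2,
            x3 * (x1 - p.c) + p.b1,
            -p.omega2 * y2 - y3 + p.C * (x1 - y1),
            p.omega2 * y1 + p.a2 * y2,
            y3 * (y1 + c_resp) + p.b2,
        ],
        axis=-1,
    )


def _rk4_step(f, y, dt):
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


_DIVERGENCE_LIMIT = 1e8


def _integrate_batch(f, y0, dt, stride, n_samples, transient_steps):
    """Fixed-step RK4 over a batch of initial states (n_reps, dim).

    Records the state at the end of the transient and then every
    ``stride`` steps.  Returns (samples (n_reps, n_samples, dim),
    ok mask) where ok is False for realizations that left the finite /
    bounded region."""
    y = np.asarray(y0, float).copy()
    n_reps, dim = y.shape
    out = np.empty((n_reps, n_samples, dim))
    ok = np.ones(n_reps, dtype=bool)

    def check(y):
        bad = ~(np.isfinite(y).all(axis=1)
                & (np.abs(y) < _DIVERGENCE_LIMIT).all(axis=1))
        if bad.any():
            ok[bad] = False
            y[bad] = 0.0  # park to avoid overflow warnings
        return y

    for _ in range(transient_steps):
        y = check(_rk4_step(f, y, dt))
    out[:, 0] = y
    for k in range(1, n_samples):
        for _ in range(stride):
            y = check(_rk4_step(f, y, dt))
        out[:, k] = y
    return out, ok


def _flow_ensemble(f, draw_init, p, seeds):
    """Resample-on-divergence driver for the flows, batched over an
    ensemble of realizations.

    Each realization draws its initial condition (and any divergence
    resamples) from its own seeded generator, so the batched result is
    bit-identical to integrating each realization alone: RK4 on a
    stacked state array is purely elementwise.
    """
    stride = int(round(p.sample_every / p.dt))
    transient_steps = int(round(p.transient_time / p.dt))
    n_reps = len(seeds)
    rngs = [np.random.default_rng(int(s)) for s in seeds]
    out = np.empty((n_reps, p.L, 6))
    init = np.vstack([draw_init(r, 1) for r in rngs])
    initial_used = init.copy()
    pending = np.arange(n_reps)
    resamples = 0
    for attempt in range(MAX_RESAMPLES + 1):
        traj, ok = _integrate_batch(
            f, init[pending], p.dt, stride, p.L, transient_steps
        )
        good = pending[ok]
        out[good] = traj[ok]
        initial_used[good] = init[good]
        pending = pending[~ok]
        if pending.size == 0:
            break
        if attempt == MAX_RESAMPLES:
            raise SimulationError(
                f"flow integration diverged after {MAX_RESAMPLES} resamples "
                f"(params={p})"
            )
        resamples += pending.size
        for row in pending:
            init[row] = draw_init(rngs[row], 1)
    return out, initial_used, resamples


def _draw_init_rossler_lorenz(rng, n):
    init = np.empty((n, 6))
    init[:, 0:2] = rng.uniform(-5, 5, size=(n, 2))   # Rössler x1, x2
    init[:, 2] = rng.uniform(0, 2, size=n)           # Rössler x3
    init[:, 3:5] = rng.uniform(-10, 10, size=(n, 2))  # Lorenz y1, y2
    init[:, 5] = rng.uniform(10, 30, size=n)         # Lorenz y3
    return init


def _draw_init_rossler_rossler(rng, n):
    init = np.empty((n, 6))
    init[:, 0:2] = rng.uniform(-5, 5, size=(n, 2))
    init[:, 2] = rng.uniform(0, 2, size=n)
    init[:, 3:5] = rng.uniform(-5, 5, size=(n, 2))
    init[:, 5] = rng.uniform(0, 2, size=n)
    return init


_FLOW_CHANNELS = ["x1", "x2", "x3", "y1", "y2", "y3"]


def rossler_lorenz_ensemble(params: RosslerLorenzParams, seeds) -> np.ndarray:
    """Integrate many Rössler–Lorenz realizations in one batched RK4
    pass (one seed per realization); returns (n_reps, L, 6).  Each row
    is bit-identical to ``simulate_rossler_lorenz`` with that seed."""
    params.validate()
    traj, _, _ = _flow_ensemble(
        lambda y: rossler_lorenz_field(y, params.a, params.C),
        _draw_init_rossler_lorenz, params, list(seeds),
    )
    return traj


def rossler_rossler_ensemble(params: RosslerRosslerParams, seeds) -> np.ndarray:
    """Batched-ensemble counterpart of ``simulate_rossler_rossler``."""
    params.validate()
    traj, _, _ = _flow_ensemble(
        lambda y: rossler_rossler_field(y, params),
        _draw_init_rossler_rossler, params, list(seeds),
    )
    return traj


def simulate_rossler_lorenz(params: RosslerLorenzParams) -> TimeSeriesSet:
    """Integrate the Rössler–Lorenz system; returns the 6-channel set
    (x1..x3, y1..y3) of ``L`` samples taken every ``sample_every`` time
    units after discarding ``transient_time``."""
    params.validate()
    traj, init, resamples = _flow_ensemble(
        lambda y: rossler_lorenz_field(y, params.a, params.C),
        _draw_init_rossler_lorenz,
        params,
        [params.seed],
    )
    meta = {
        "system": "rossler_lorenz",
        "params": asdict(params),
        "initial_state": init[0],
        "resamples": resamples,
    }
    return TimeSeriesSet(traj[0], _FLOW_CHANNELS, dt=params.sample_every, meta=meta)


def simulate_rossler_rossler(params: RosslerRosslerParams) -> TimeSeriesSet:
    """Integrate the coupled Rössler–Rössler system (6 channels)."""
    params.validate()
    traj, init, resamples = _flow_ensemble(
        lambda y: rossler_rossler_field(y, params),
        _draw_init_rossler_rossler,
        params,
        [params.seed],
    )
    meta = {
        "system": "rossler_rossler",
        "params": asdict(params),
        "initial_state": init[0],
        "resamples": resamples,
    }
    return TimeSeriesSet(traj[0], _FLOW_CHANNELS, dt=params.sample_every, meta=meta)


# ---------------------------------------------------------------------------
# measurement noise and standardization
# ---------------------------------------------------------------------------

def add_noise(series: TimeSeriesSet, spec: NoiseSpec) -> TimeSeriesSet:
    """Add Gaussian white measurement noise at ``spec.snr_db`` decibels.

    Per channel the noise standard deviation is
    sigma_signal * 10**(−snr_db/20).  The input set is left untouched.
    """
    rng = np.random.default_rng(spec.seed)
    values = series.values.copy()
    for j, name in enumerate(series.channel_names):
        sigma = float(np.std(values[:, j]))
        if sigma == 0.0:
            raise DataError(f"channel {name!r} is constant; SNR undefined")
        noise_sd = sigma * 10.0 ** (-spec.snr_db / 20.0)
        values[:, j] = values[:, j] + rng.normal(0.0, noise_sd, size=len(values))
    meta = dict(series.meta)
    meta["noise"] = {"snr_db": spec.snr_db, "seed": spec.seed}
    return TimeSeriesSet(values, list(series.channel_names), dt=series.dt, meta=meta)


def standardize(series: TimeSeriesSet) -> TimeSeriesSet:
    """Return a copy with every channel at sample mean 0 and sample
    standard deviation 1 (divisor n−1)."""
    values = series.values.copy()
    for j, name in enumerate(series.channel_names):
        values[:, j] = standardize_channel(values[:, j], name)
    return TimeSeriesSet(
        values, list(series.channel_names), dt=series.dt, meta=dict(series.meta)
    )


def standardize_channel(x: np.ndarray, name: str = "series") -> np.ndarray:
    x = np.asarray(x, float)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0:
        raise DataError(f"channel {name!r} is constant; cannot standardize")
    return (x - np.mean(x)) / sd
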