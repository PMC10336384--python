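# Methods

`crosscause` benchmarks two attractor-reconstruction causality
detectors — continuity scaling (CS) and convergent cross sorting
(CCS) — on coupled chaotic systems, and exposes both detectors for
arbitrary two-column time series.  This note records the models, the
estimator definitions, the defaults and the numerical choices, and what
the synthetic benchmarks do and do not establish about real data.

## State-space causality

Both detectors start from Takens' delay reconstruction: from a scalar
series s_t, build points X_t = (s_t, s_{t−τ}, …, s_{t−(d−1)τ})
(backward, most-recent-first; the first valid time is (d−1)τ with
0-based indexing).  If x drives y, the response y encodes the driver's
state, so the reconstruction L_y of the *effect* unfolds the joint
dynamics and there is a continuous map from L_y to L_x.  Both scores
for "x causes y" therefore interrogate the effect's geometry:
neighborhoods are formed in L_y and their images are examined in L_x.
The wrong direction shows little structure — unless the coupling is so
strong that the response becomes a function of the driver (generalized
synchronization), in which case *both* directions show structure and
directional inference is ill-posed; see Limitations.

## Continuity scaling (CS)

For n_ref reference points in L_y and a log-spaced grid of radii ε,
collect the times falling in the ε-ball around each reference and
measure the pre-image radius δ(ε): the mean distance, in L_x, from the
reference's matching point to the members' matching points.  Under a
continuous map δ grows ∼ log ε; the causal strength is the ordinary
least-squares slope of δ against ln ε (the fit R² is reported so poor
scalings can be rejected).  Both channels are standardized (mean 0,
sample sd 1) before embedding, so the strength is exactly invariant
under positive affine transforms of either series.

Choices that needed deciding:

* **Pre-image radius statistic.** The radius of the smallest ball
  containing all members (the farthest member) is biased under the
  null: the maximum of m unrelated distances grows with the member
  count m, which grows with ε, so independent series — especially with
  unbounded marginals — show a large spurious slope (measured: ≈0.7 for
  independent Gaussians, versus ≈0.12 for a genuinely coupled logistic
  pair).  The default is therefore the *mean* member distance, which is
  flat under the null (measured ≈0.002 on the same nulls) and preserves
  the log-scaling under coupling; `radius_stat='max'` retains the
  containing-ball variant.
* **ε grid.** Log-spaced from the 1st to the 50th percentile of the
  pairwise distances of the effect cloud (n_eps = 12 levels).  Balls at
  the smallest radii are often under-populated on thin attractors; the
  slope fit starts at the smallest level where at least half the
  reference balls have ≥ 3 members, and averages one fixed reference
  set from there on.  Because balls nest, this makes the aggregated
  δ(ε) exactly non-decreasing.  If more than half of all
  (reference, ε) cells are under-populated the call fails with advice
  to raise the minimum ε.
* **Aggregation.** Mean over reference points (median by flag);
  n_ref = 200 seeded uniformly over valid times.

## Convergent cross sorting (CCS)

CCS replaces distances by dimensionless ranks.  Over a seeded sample of
up to 20 000 point pairs (all pairs when fewer), pairwise distances in
each reconstruction are rank-transformed to evenly spaced values in
[0, 1] (ties share the mean rank).  Sorting the pairs by their
effect-space distance, the normalized sorting error

E(R) = mean |R_x − R_y| over pairs with R_y ≤ R, divided by 1/3,

is ≈ 1 for unrelated series at every R (1/3 is E|U−V| for independent
uniforms, the random-sorting expectation) and dips toward 0 at small R
under coupling.  E(R), evaluated at 20 levels, is fitted by
a + b·e^{cR} with bounds a ∈ [0, 2], b ∈ [−2, 2], c < 0; the fit is a
variable-projection least squares (closed-form (a, b) on a grid of 64
decay rates c), which is deterministic and robust.  If the fit fails,
E(0) is linearly extrapolated from the two smallest-R values and the
result is flagged.

The causality score is max(0, 1 − E(0)) with E(0) = a + b: independent
series score ≈ 0, and strong coupling saturates the score at 1.  (The
raw intercept E(0) is a sorting *error* — small when causal — so the
score is its complement; the rank curve and intercept are both kept in
the result for audit.)  The whole pipeline is rank-based, hence exactly
invariant under positive affine transforms of either series.

The underlying CCM cross-map is also exposed: reconstruct the target
from the source embedding's d+1 nearest neighbors with weights
e^{−d_i/d_1} normalized to sum 1, and report the Pearson correlation ρ
between target and reconstruction.  Zero nearest-neighbor distances
degenerate the weights to uniform over the zero-distance set.

## Embedding defaults

The benchmark systems never come with printed embedding parameters, so
the defaults are the package's own choices and every result records the
values used.

* **Maps** (logistic): dim 2, lag 1, no Theiler window.
* **Flows** (Rössler–Lorenz, Rössler–Rössler): lags are data-driven —
  the earlier of the first autocorrelation minimum and the first 1/e
  crossing, floor 1.  Dimensions are *role-based*: the cause
  reconstruction only has to unfold the cause's own attractor (dim 4),
  while the effect reconstruction must unfold the joint dynamics
  written into it by the coupling, so it gets the Takens-style doubled
  dimension (dim 8).  The same policy applies to both scored
  directions, keeping the comparison symmetric.  A Theiler window of
  effect-dim × effect-lag excludes trivially autocorrelated neighbors.

On user data (`score_file` / the CLI) with `embedding='auto'`, lags are
selected per channel; if both come out 1 the data are treated as
map-like (dim 2), otherwise the flow policy applies.

## Benchmark systems

* **Logistic pair**: x_i(t+1) = x_i(t)[r_i − r_i x_i(t) − C_i x_j(t)],
  r1 = 3.6, r2 = 3.7; C2 couples x1 into x2 (so C2 > 0 means
  x1 → x2).  Initial conditions ~ U(0.05, 0.95); 1000-step transient
  discarded; trajectories leaving [0, 1] (possible at strong coupling)
  are rejected and resampled up to 20 times, with the resample count in
  the output metadata.
* **Networks**: 20 logistic maps in a chain (19 directed edges) or ring
  (20 edges), growth rates uniformly spaced on [3.6, 3.8], a common
  edge coupling (default 0.1).  Both the rate vector and the edge
  coupling are explicit fields, so alternative readings cost one
  config change.
* **Rössler–Lorenz**: a Rössler oscillator time-scaled by a (default 6)
  drives a Lorenz system through +C·x2² in the dy2/dt equation; the
  classic constants 0.2, 5.7, 10, 28, 8/3 are fixed.  The scored pair
  is (x2, y2).
* **Rössler–Rössler**: two Rössler oscillators with angular frequencies
  ω1 (driver) and ω2 (response), diffusive coupling C(x1 − y1) in the
  dy1/dt equation; shape parameters default to the canonical
  a = 0.15, b = 0.2, c = 10 and C = 0.1, all overridable.  The response's
  third equation uses the standard Rössler sign y3(y1 − c) + b2 by
  default; the non-standard +c variant sits behind ``y3_sign='plus'``.
  The frequency ratio r = ω1/ω2 is always derived, never stored.
* **Integration**: fixed-step classical RK4, dt = 0.005, 500 time units
  of transient discarded, then one sample every 0.3 time units —
  deterministic and reproducible, adequate for these non-stiff systems.
  Divergent realizations (non-finite or |state| > 1e8) are resampled
  like logistic rejections.  Ensembles integrate as one batched state
  array; per-realization seeds drive all draws, so batched and
  one-at-a-time runs are bit-identical.
* **Measurement noise**: added after simulation (never fed back),
  per-channel Gaussian with σ_noise = σ_signal·10^(−SNR_dB/20),
  independent across time and channels.

## Significance, AUC and the experiment designs

* **Stationary bootstrap**: surrogates of the *candidate cause* with
  geometric block lengths (circular wrap-around), destroying the
  cross-dynamics while preserving the marginal and short-range
  autocorrelation.  The mean block length defaults to the automatic
  Politis–White rule (flat-top-kernel spectral estimates with the
  standard insignificance cutoff for the lag window), overridable.
  p = (1 + #{surrogate ≥ observed}) / (1 + n_surrogates), so the
  smallest attainable p at 100 surrogates is 1/101.
* **AUC**: rank-based P(pos > neg) + ½P(pos = neg) (midranks; equals
  the normalized Mann–Whitney U, verified against a brute-force count).
  Truth labels derive only from the generating couplings: direction
  i → j is positive iff the coupling of i into j's equation is > 0.
* **Sweeps** (length, coupling, noise, frequency): per level,
  realizations with derived seeds are scored in both directions by both
  methods; the per-level AUC uses the raw scores.  Per-realization
  diagnostics (correlation, KSG mutual information with k = 4 in nats,
  Kozachenko–Leonenko entropies) can be attached to every record.
  Levels with > 20% realization failures are dropped and reported.
* **Bidirectional grid**: logistic pairs on a (C1, C2) grid over
  [0, 1]; per cell, realization and direction both the strength and a
  bootstrap p-value are computed, with simulations and surrogate draws
  shared across methods so the method comparison is paired.  The
  headline grid efficiency is the rank-based AUC on 1 − p; the summary
  also carries the detection-call quantities — TPR and FPR at the
  p ≤ 0.05 threshold and the binary-detector AUC ½(1 + TPR − FPR) —
  for audit.  RMSE compares the mean detected-strength map per direction
  (and the between-direction difference map) with the actual couplings
  after min–max rescaling the detected map onto the actual range —
  strength and coupling live in different units, so this comparison is
  approximate by construction.
* **Causality ratio**: r_c(1→2) = C(1→2)/C(2→1) with both strengths
  floored at 1e-6 (floored results are flagged); recommended over raw
  strengths as the relative indicator.
* **Seeds**: every realization's seed derives from the master seed plus
  its (design, level, rep) coordinates via a CRC-keyed SeedSequence, so
  any single cell reruns in isolation; identical config + seed
  reproduce every output byte-for-byte.

## Desk-scale problem sizes

The reference experiments are reproduced at reduced scale, chosen so
the whole battery runs on one CPU core in well under an hour: the
bidirectional grid uses a 9×9 grid, 10 realizations per cell and 50
surrogates (full scale: 25×25, 50, 100); sweeps use 200–300
realizations per level (full scale: 1000).  Scaled AUCs carry more
sampling noise — roughly ±0.03 at these sizes — which is the dominant
uncertainty when comparing against the full-scale values.

## What the synthetic benchmarks do and do not show

The generators emulate exactly the structures the detectors are
designed for: low-dimensional deterministic chaos, unidirectional or
bidirectional coupling of known strength, and additive measurement
noise.  They do not emulate process noise, nonstationarity,
seasonality, observation gaps, or mixed time scales — all common in
field data.  Passing benchmarks therefore establishes that the
detectors recover known couplings in clean chaotic regimes at realistic
series lengths (n ≈ 150–500), not that they are reliable on seasonal or
strongly stochastic records; on such data the significance test and the
convergence-with-length check are the guardrails, and strong shared
periodicity remains a known confounder.

## Known limitations

* **Generalized synchronization**: once the response is a function of
  the driver's state, both directions show continuity and rank
  agreement; detection flips or saturates (visible in the grid at
  strong bidirectional coupling and in the Rössler–Lorenz system at
  large C).  Neither method can resolve direction there; the mutual
  information diagnostic flags the regime but its "high" threshold is
  system-relative and left to the user.
* **Frequency mismatch**: with a large main-frequency ratio between
  driver and response, both detectors tend to report causality from the
  slow to the fast variable regardless of the true direction (the
  Rössler–Rössler sweep shows the reversal at small r = ω1/ω2).
* **Strength units**: CS slopes and CCS scores are not in coupling
  units; only their ordering and ratios are meaningful, hence the
  min–max rescaling caveat on grid RMSE values and the recommendation
  to report r_c.
* **Noise floor**: below roughly 15 dB SNR the directional signal in
  the logistic benchmark is lost; the residual reverse-leakage of the
  driven series' coarse component can even push the AUC slightly below
  chance before both directions die out.
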