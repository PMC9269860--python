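# Methods

This note documents the models, conventions and numerical choices behind
`iemgprop`, and what the synthetic experiments do and do not demonstrate.

## The control scheme under evaluation

One iEMG channel drives one normalized joint-force output. A feature
operator is evaluated over a causal sliding window of the comb-filtered
iEMG; the value is assigned to the newest window sample, so the series is
usable online. The series is divided by its maximum over the first two
sine-tracking periods (two-repetition calibration); tracking periods 3..R
serve only for evaluation. Estimates are clipped at zero but not at one —
overshoot is informative and clipping would distort the RMSE. No smoothing
is applied beyond the analysis window itself.

Performance is scored per (channel, movement) segment by

* `RMSE (%)` — 100 × root-mean-square difference between the normalized
  measured and estimated force, sample-aligned with **no** lag
  compensation (the window's group delay therefore counts as error, which
  is the honest online view), and
* zero-lag Pearson correlation, a complementary shape measure.

## Feature conventions

All fourteen operators act on windows of `N = round(width_ms · fs / 1000)`
samples; widths 50–1050 ms in 100 ms steps (50–550 ms for SSC/ZC/WA) and a
10 ms evaluation increment by default (increment 1 is available and
oracle-tested; results at larger increments are exact subsamples).

* `Var` uses the zero-mean simplification `Σx²/(N−1)`: the iEMG mean is
  ~0 and the simplification is the form used in embedded practice.
* `ZC` counts sign changes of consecutive samples gated by an amplitude
  dead zone `|x_n − x_{n+1}| ≥ thr`; `SSC` counts slope-sign products
  `(x_n−x_{n−1})(x_n−x_{n+1}) ≥ thr`; `WA` counts threshold-exceeding
  consecutive differences. Dead zones resolve to `Q × MAV(rest)` with
  `MAV(rest)` taken over the first 100 ms of the segment (a rest interval
  by protocol). Because the SSC indicator acts on a product of two
  amplitudes (µV²), the resolved dead-zone value is squared for SSC so one
  Q grid serves all three counters.
* Spectral operators use the one-sided magnitude-squared DFT of the raw
  window — rectangular taper, no padding, no detrending: `P_n = |X_n|²`,
  `f_n = n·fs/N`, `M = ⌊N/2⌋+1` bands. `Etot = Σ_{n<M} P_n/(M−1)`,
  `Tf = Σ_{n<M} P_n f_n²`, `Tf_mod = Σ_{n<M} P_n f_n` (DC included, last
  band excluded, exactly as the formulas are printed in the embedded-EMG
  literature); `MNF` and `MDF` sum over all `M` bands. Under this scaling
  Parseval reads `Σx² = (P_0 + 2ΣP_mid + c·P_last)/N` with `c = 1` for
  even `N`.
* `Ttd` applies the Teager–Kaiser operator `ψ_n = x_n² − x_{n−1}x_{n+1}`
  (for a pure sinusoid, exactly `A² sin² ω`) followed by a moving average
  of the window width. `ψ_n` needs one future sample, so the causal series
  at newest sample `i` averages the `N` most recent fully available values
  (centers `i−N .. i−1`, clipped at the signal start).
* `FR` detects action potentials as rising crossings of `|x|` above a
  quantile threshold (85th–99th of the rectified first full tracking
  period) with a 5 ms dead time — the typical MUAP duration — so one
  multiphasic potential is counted once. The exact detector of the
  original embedded implementation is not public; this
  crossing-plus-dead-time detector is a declared stand-in. The sliding
  implementation restarts the dead-time greedily at each window start
  (matching a per-window detector) and is computed with a binary-lifting
  successor chain so the per-window scan stays vectorized.

Every sliding implementation is required to match a naive per-window
re-evaluation exactly (counts) or to 1e-9 relative (floats); this oracle
equivalence is part of the test suite, so any faster implementation remains
contractually identical to the definitional one.

## Pre-processing

Powerline interference is removed with a comb of third-order Butterworth
band-stop sections (f₀ = 50 Hz, ±2 Hz) at every harmonic below 0.9 × the
Nyquist frequency by default (configurable; the synthetic generator only
emits five harmonics and tests use a five-section comb). Filtering defaults
to causal operation, matching the online intent; zero-phase
forward-backward filtering is available for offline parity studies. The
causal comb needs a few hundred milliseconds to settle, so the leading rest
window of the very first segment carries some warm-up transient — real
recordings start earlier than the first cue, so this only affects
synthetic sessions, and only the rest-MAV of the first movement.

Force gauge signals are split into positive and negative phases
(`max(x,0)`, `max(−x,0)`), each phase normalized per movement by its
maximum over the calibration span. Channel–gauge–movement pairing evaluates
the normalized 250 ms MAV estimate of every channel against every
(gauge, phase, movement) candidate and keeps the minimal-RMSE triple. The
package implements this RMSE refinement as the sole pairing criterion; the
original workflow's manual SNR-based pre-selection is not reproduced, as
only the RMSE step is operationally defined.

## Synthetic sessions

The generator emulates the recording protocol: per movement, one rest
second followed by ten 0.1 Hz sine-tracking periods at 20 % MVC; 6
differential iEMG channels at 10 kHz; 9 force gauges (fingers D2–D5,
thumb ×2, wrist ×3) with flexion/extension phase signs.

* **Tracking error**: the elicited force is the target sine plus Gaussian
  noise low-passed at 1 Hz with 2 % MVC RMS (causal filter with a
  discarded warm-up margin, so the trace has no edge artifacts), clipped
  at zero. The same trace drives the muscle and the gauge — it *is* the
  true force.
* **Motor units**: the default pool has 5–30 units per channel,
  recruitment thresholds uniform in [0, 0.5), rates 8–35 Hz with slope
  40 Hz per unit excitation, ISI coefficient of variation 0.15, lognormal
  MUAP amplitudes (median 60 µV, σ = 0.5) shaped as first/second Gaussian
  derivatives of 5 ms duration. Spikes are placed by time rescaling: the
  instantaneous rate is integrated and spikes fall where the integral
  crosses jittered unit-mean targets, which preserves the closed-form rate
  under constant drive (the basis of the rate-recovery test).
* **Noise**: 3 µV RMS Gaussian baseline plus 50 Hz powerline at 50 µV with
  five decaying harmonics and random phases — the interference deliberately
  exceeds the iEMG scale so the comb filter is load-bearing.
* **Crosstalk**: each channel receives every other movement's excitation
  at a configurable gain (default 0.1); gauges add white noise at 20 dB
  SNR by default.

A second pool configuration, `proportional_units`, sets all thresholds to
zero with rate linear in excitation, making the aggregate rectified iEMG
proportional to the driving force. Recovery experiments use it because it
isolates pipeline error from physiology: with recruitment, the MAV–force
relation is convex (units switch in at their minimum rate) and the
best-case RMSE of simple features saturates near 20 % — which is precisely
the regime the evaluated control scheme operates in on real recordings.

What the generator does **not** model: fatigue, electrode migration,
conduction-velocity and MUAP-shape variability, force-gauge drift, or
motor-unit synchronization. Passing recovery tests therefore demonstrates
correctness of the pipeline under its stated assumptions, not expected
performance on any particular patient recording.

## Statistics

Per-algorithm distributions pool the best grid cell per (segment,
algorithm), ties broken toward the smaller window (lower controller
latency) and then the smaller threshold. Channels flagged `poor` in a
database manifest are excluded from aggregation. Normality is screened
with the Lilliefors-corrected Kolmogorov–Smirnov test (statsmodels);
because the metric distributions are non-normal, algorithms are compared
with the Friedman test on within-block ranks (scipy; the textbook χ²
formula for the two-algorithm case) followed by Dunn-type pairwise
mean-rank comparisons, `z = |R̄_i − R̄_j| / √(k(k+1)/6n)`, Bonferroni-
corrected over all pairs and gated on a significant omnibus test. The post
hoc flags are verified to agree with an exact binomial sign test in the
two-column case and to keep the family-wise error below nominal on
exchangeable columns.

## Problem sizes

Desk-scale checks (operator oracles, filter responses, statistics
calibration) run in seconds. The synthetic studies use: 20 single-movement
proportional-drive sessions with the full 10 repetitions for force
recovery; 20 six-movement sessions at 3 repetitions for pairing accuracy;
and 2-movement sessions at 3–4 repetitions for full-grid sweeps (the grid
itself — 653 cells per segment — is always complete). These sizes were
chosen so the whole evaluation reruns from scratch in a few minutes while
keeping every stage's statistics meaningful; all of them are parameters,
not constants, and scale up directly.

## Known limitations

* Criterion-level reproduction of the published headline medians requires
  the deposited fine-wire database (Matlab containers); the loader and the
  aggregation path are implemented, but the numbers can only be recomputed
  once those files are placed under `data/real/`.
* The `.mat` loader maps fields through a configurable dictionary because
  the container schema is not described in the evaluation itself; the
  defaults follow the obvious naming and will need one-line adjustment to
  the database's actual field names.
* With causal filtering, the first segment's rest window includes filter
  warm-up (see above); zero-phase mode avoids this at the cost of
  non-causality.
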