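# Methods

## The sprint model

A maximal short sprint from a (near) standing start is modelled by the
mono-exponential velocity law `v(t) = MSS·(1 − exp(−(t + TC)/TAU))`. The
model implies a linear acceleration–velocity relation
`a(v) = MAC·(1 − v/MSS)` with `MAC = MSS/TAU`, and a relative propulsive
power curve `P(v) = v·a(v)` peaking at `PMAX = MSS·MAC/4`. These two
identities are the standard parameter definitions of the mono-exponential
sprint model as used by the open-source sprint-profiling ecosystem; a
profile object enforces both to a relative 1e−9 unless it is flagged as a
cross-trial aggregate (see below). The time correction TC is unconstrained
in sign and bounded by |TC| ≤ 1 s during fitting; it exists to absorb
start-trigger offset and is reported only by the time–velocity method
(the a–v line contains no time information).

## Time–velocity estimator

Input traces are filtered by keeping samples with v ≥ 0.75 m/s up to the
first occurrence of the trace's maximum velocity; the trace is assumed
already smoothed by the recording instrument and is not re-smoothed.
The fit minimises `Σ w_i (v_i − v̂(t_i))²` over (MSS, TAU, TC) with
`w_i = t_i` rescaled to mean 1 (the "later samples count more" convention;
the functional form of the weight is a package choice — linear in time is
the simplest monotone option and is configurable to uniform). The time
origin is re-zeroed to the first retained sample, which makes the
estimates invariant to uniform time shifts (absorbed into TC).

Numerics: trust-region reflective least squares with analytic Jacobian;
bounds MSS ∈ (0, 15] m/s, TAU ∈ (0, 5] s, TC ∈ [−1, 1] s; tolerances
1e−12 on cost, step and gradient; starting values MSS₀ = observed peak,
TAU₀ = 1 s, TC₀ = 0, with restarts at TAU₀ ∈ {0.5, 0.8, 1.2, 1.5} and the
lowest-cost converged solution kept. A fitted MSS below 0.99 × the
observed peak velocity is flagged (not fatal). The reported residual
standard error is the unweighted root mean square residual with
df = n − 3.

## Velocity–acceleration (in-situ) estimator

Samples with a > 0 m/s² and v > 3 m/s (both strict) are pooled across all
of an athlete's sprints, binned into half-open 0.2 m/s velocity intervals
anchored at the 3 m/s filter threshold, and the two highest-acceleration
samples per bin are retained (ties keep the earlier sample; fewer than two
non-empty bins is an error since the line is then underdetermined). A
weighted straight line `a = b0 + b1·v` is fitted with weights `w_i = v_i`
rescaled to mean 1; a non-negative slope or non-positive intercept is
rejected as non-physical. Then MAC = b0, MSS = −b0/b1, TAU = MSS/MAC,
PMAX = MSS·MAC/4.

Per-trial fits are also supported; per-trial profiles (from either
method) are combined by the *best-value aggregate*: maximum of MSS, MAC
and PMAX, minimum of TAU. The aggregate may mix trials, so the
MAC = MSS/TAU identity is deliberately suspended on aggregate profiles
and they are marked as such.

Note an intrinsic property of the envelope selection: with symmetric
zero-mean acceleration noise, taking per-bin maxima biases the selected
accelerations upward, and unevenly so when bin occupancy varies along the
velocity axis (bins near the velocity plateau collect many more samples).
The test suite checks the upward direction of this selection bias in a
controlled setting with uniform bin occupancy.

## Sprint detection in continuous streams

Tracking devices record whole sessions, so sprints are recognised by
thresholds: a window opens where velocity crosses 3 m/s upward and the
ensuing local maximum reaches 5 m/s; the start is pushed back to the last
near-stationary sample (v < 0.5 m/s, the athlete's set position), bounded
by 8 s before the trigger; the window closes when velocity falls back
below the trigger (capped at 8 s); windows closer than 2 s are merged and
edge-clipped windows are flagged truncated. The thresholds are calibrated
so that a maximal 30 m sprint (peak 7–10 m/s) is always captured while
jogging and shuffling (peaks below 5 m/s) are rejected; all are exposed
as arguments and CLI options.

## Agreement and sensitivity statistics

With device value `y` and criterion value `x`, the percent difference is
`%Diff = 100·(y − x)/x`, computed per observation unit — per *trial* for
the time–velocity comparison (trials treated as independent) and per
*athlete* for the in-situ comparison (one pooled profile per athlete).

* `%Bias` — mean of %Diff.
* `%MAD` — mean |%Diff_i − mean(%Diff)| (deviation about the mean). A
  `raw` mode (mean |%Diff_i|) is available for sensitivity analysis.
* `%RSE` — from OLS of device on criterion,
  `sqrt(Σ(100·(y_i − ŷ_i)/ŷ_i)² / (N − 2))`; residuals are percentised
  against the *fitted* values. Treating the criterion as error-free, this
  is the device's percent SEM.
* `%MDC95 = %RSE·√2·1.96` — the smallest change in the device measure
  interpretable, with 95% confidence, as a real change.

Interval estimates use the bias-corrected and accelerated (BCa) bootstrap
with 5000 resamples at the observation-unit level: the bias-correction
constant comes from the fraction of the bootstrap distribution below the
point estimate and the acceleration constant from jackknife skewness.
The implementation is authored here (and cross-checked against SciPy's
independent BCa in the tests); statistics undefined on degenerate
resamples signal NaN and are excluded. Because %MDC95 is a fixed positive
multiple of %RSE and BCa intervals are equivariant under monotone
transformations, the %MDC95 interval is the scaled %RSE interval. Each
interval is classified against the practical band — ±5% for %Bias, and
[0, 5%] for the non-negative metrics — as `within`, `overlapping` or
`outside`.

## Synthetic study generator

The generator emulates a concurrent-validity session: `n_athletes = 30`
athletes with true profiles drawn uniformly from MSS ∈ [7, 10] m/s,
TAU ∈ [0.9, 1.5] s, TC ∈ [0.05, 0.30] s; 1–3 maximal 30 m sprints each
(uniform over {1, 2, 3}); a 1000 Hz criterion trace per sprint and one
continuous 20 Hz device stream per athlete.

*Criterion*: model velocity sampled until the analytic distance reaches
30 m, plus white Gaussian noise (sd 0.03 m/s) removed by a zero-phase
2nd-order Butterworth low-pass at 10 Hz — a documented stand-in for the
(undisclosed) vendor smoother. Noiseless traces pass through untouched.

*Device stream*: piecewise clean velocity — walking filler (bounded
random walk in [0.5, 2] m/s for 30–90 s), a stationary 8–15 s set phase
before each sprint, the mono-exponential sprint to 30 m, and an
exponential deceleration (time constant 1 s) back to walking pace. The
error model has three layers, emulating a sensor-fused tracking export:

* velocity: white noise (sd 0.10 m/s) plus an AR(1) component
  (sd 0.06 m/s, correlation time 0.5 s) standing in for
  positional-filtering error;
* acceleration: the true acceleration scaled by a fixed per-athlete gain
  `1 + N(0, 0.05)` (sensor mounting/fusion calibration of that athlete's
  unit), plus AR(1) (sd 0.05 m/s²) and white (sd 0.05 m/s²) additive
  noise.

The acceleration channel is modelled as a device-reported, sensor-fused
signal rather than as a derivative of the noisy velocity: naively
differentiating 20 Hz velocity with white noise of sd 0.10 m/s yields
acceleration noise near 0.4 m/s² sd, an order of magnitude beyond the
validated accuracy of fused tracking accelerometry, and its envelope
selection then dominates every agreement metric. The gain term is the
load-bearing design choice: MSS, being a ratio of intercepts, is
invariant to an acceleration scale error, while MAC, TAU and PMAX inherit
it in full — which reproduces the characteristic robustness ordering
(MSS far more stable than the acceleration-side parameters) that
motivates the whole comparison. Noise magnitudes were calibrated once so
that the dispersion of device–criterion percent differences and the
resulting %MAD/%MDC95 ranges land in the low-single-digit /
~10–15-percent regimes typical of 20 Hz tracking validations; they are
config fields, not claims about any particular hardware.

What the generator does *not* emulate: multipath/occlusion dropouts,
heteroscedastic error growth with speed, curved running paths,
within-athlete fatigue across trials, and the vendor's proprietary
criterion smoothing. Passing tests therefore demonstrate correctness and
calibration of the pipeline under a plausible error structure, not a
validity claim for any specific device.

The end-to-end run pairs criterion and device time–velocity fits per
trial, pairs best-aggregated criterion values with the pooled in-situ fit
per athlete, and computes the agreement report with unit-level BCa
resampling. Athletes with no detected sprint are dropped with a warning.
All randomness flows from a single seed through named child streams, so a
fixed configuration reproduces its report bit for bit.

## Problem sizes used in the checks

The automated checks run the full study at its default size (30 athletes,
~60 trials): once with every noise source disabled (the two methods must
then agree with the criterion to within 0.5% bias, the residual being
20 Hz discretisation), and across 20 replicate seeds for the ordering of
%MDC95 (MSS smallest, the others at least two-fold larger). Bootstrap
calibration is checked by coverage of the 95% BCa interval for a Gaussian
mean (n = 30, 1000 replicates), and the selection and BCa machinery
against exhaustive and SciPy oracles respectively.

## Known limitations

* The ±5% practical band and the 0.2 m/s bin width are conventions, not
  fitted quantities; both are configurable.
* The best-value aggregate intentionally breaks the parameter identities;
  downstream code must treat aggregate profiles as tuples of per-metric
  extrema, not as a single coherent profile.
* %RSE percentises residuals against fitted values, so it is undefined
  when the fitted regression line produces non-positive values — possible
  only for degenerate inputs far from physiological ranges.
* The sprint detector assumes a near-stationary set phase before each
  sprint; rolling starts would need the `v_start` threshold raised.
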