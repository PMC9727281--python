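# Methods

## Model and measurement chain

A passive stretch rotates the ankle from 20° of plantarflexion to 0°
(angles are positive plantarflexion, decreasing during the stretch) at
a nominal velocity *v*. When the joint crosses the muscle's reflex
threshold angle θ the stretch reflex is mechanically initiated at the
spindles; the reflex burst appears in the surface EMG one monosynaptic
latency ℓ later. The measurable EMG onset time t_on therefore satisfies
θ(t_on − ℓ) = θ_true, and on a constant-velocity segment

- uncorrected threshold: SRT(v) = θ_true − ℓ·v,
- corrected threshold: SRT_corr(v) = angle(t_on − ℓ) = θ_true.

The SRT-vs-velocity ordinary least squares (velocity on the x-axis) has
the corrected-minus-uncorrected slope difference +ℓ, and its y-intercept
is the tonic stretch reflex threshold (TSRT). ℓ is taken per subject
and muscle from the H-reflex latency: the stimulus-to-initial-deflection
time of the electrically evoked monosynaptic response, whose pathway
matches the stretch reflex except for the spindle-to-popliteal-fossa
segment. That segment is bounded by 15% of the arc
(`pathway_error_bound`: 4.2 ms, i.e. 1.2° at 291 °/s for ℓ = 28 ms) and
is deliberately left uncorrected, matching field practice; the bound is
exposed so users can judge the residual.

Identities above hold only where the latency window [t_on − ℓ, t_on]
lies inside the constant-velocity segment. With the default 30 ms
acceleration phase and θ = 19° the crossing at 210–291 °/s falls inside
the acceleration ramp and SRT(v) = θ − ℓ·v is *not* exact — a property
of the kinematics, not an artifact. Exactness demonstrations therefore
use θ = 15°, which crosses post-acceleration at all four study
velocities; stochastic recovery keeps the θ = 19° default, because the
corrected threshold is insensitive to where in the ramp the crossing
happens.

## Synthetic data generator

The generator emulates the acquisition the analysis was designed for,
with these defaults (all in `SimulationConfig`):

| parameter | default | why |
|---|---|---|
| sampling_rate | 2000 Hz | standard for surface EMG; one sample = 0.5 ms, small against 23–35 ms latencies |
| velocities | 55, 110, 210, 291 °/s | the study's four ramp speeds |
| n_trials_per_velocity | 10 | the study's count |
| start/end angle | 20° → 0° | the study's range of motion |
| accel_duration | 30 ms | middle of the actuator's stated 20–40 ms |
| true_threshold_angle | 19° | an early threshold, 1° into the stretch, as observed in velocity-independent participants |
| latency (mean ± SD) | 28 ± 3 ms, clipped to 23–35 ms | the reported group H-reflex latencies |
| background_sd | 1 (unit scale) | arbitrary EMG units |
| burst_gain | 5 | a clear but not extreme reflex burst (variance ratio 26) |
| burst_rise_time | 10 ms | gradual motor-unit recruitment; burst shape is otherwise unspecified in the literature |
| mvc_rms | 50 | puts resting background at 2% MVC, below the 5% rejection bound |
| contamination_level | 10% MVC | comfortably above the rejection bound |

Background EMG is white Gaussian noise band-limited to 20–450 Hz and
scaled to unit variance; the reflex burst is an independent band-limited
component whose SD rises linearly over `burst_rise_time` to
`burst_gain × background_sd` and persists to the end of the trial. The
true threshold crossing is defined on the noiseless commanded
trajectory (constant acceleration, then constant velocity, then hold),
so ground truth does not depend on measurement noise. The H-reflex
trace has the stimulus artifact at t = 0, an optional M-wave, and a
biphasic H-wave whose deflection starts exactly at the drawn latency.

What the generator does **not** emulate: torque and muscle mechanics,
motor-unit structure in the EMG (it is Gaussian), post-activation
depression across the 2.6–2.9 s inter-stretch intervals (trials are
independent), movement artifacts, or electrode noise
nonstationarities. Passing tests therefore demonstrate correctness of
the *analysis* under the stated signal model, not robustness to every
failure mode of real recordings.

## Onset detection

The primary detector applies the approximated generalized likelihood
ratio for a variance increase in zero-mean Gaussian data. With baseline
variance σ₀² from the 500 ms pre-stretch interval (already screened by
the rejection rule, hence quiescent by construction), the statistic for
the L-sample window ending at k is g(k) = (L/2)(r − ln r − 1) with
r = σ̂₁²/σ₀²; an alarm requires a variance *increase* (r > 1) above the
decision threshold. The onset is then refined in two stages:

1. **Step-model ML scan** over the trailing window: change point j
   maximizing the likelihood of baseline variance before j and window-ML
   variance after. On an abrupt variance step this is exact (verified
   against an exhaustive scan).
2. **Ramp-foot extrapolation**: physiological bursts rise gradually, and
   the step model systematically lands a few ms *into* the rise (the
   per-sample likelihood only favours "post-change" once the envelope
   clears ~√(ln r/(1−1/r)) baseline SDs). The burst amplitude
   signed-sqrt(RMS² − σ₀²) is fitted linearly around the step estimate
   and extrapolated to zero. The stage is skipped when the dispersion of
   x² after the estimate is far below Gaussian (CV < 0.5), i.e. on
   deterministic step inputs, so step-input behaviour is unchanged; the
   extrapolated shift is also clamped to (0, 15 ms].

Defaults: test window 25 ms, decision threshold 80. The threshold was
tuned (procedure shipped as a test) so that the per-trace false-alarm
rate on 1.6 s band-limited pure-noise traces stays below 1%: filtered
20–195 Hz noise carries only ~9 effective degrees of freedom per 25 ms
window, so white-noise calibrations (threshold ≈ 10) false-alarm on
most traces.

The fallback detector mirrors the manual criterion: the rectified EMG,
smoothed with a centred 10 ms moving average, must exceed 2 baseline
SDs for at least 100 ms. "For at least 100 ms" is read as a human
would: the envelope stays above threshold for ≥80% of the forward
100 ms window (its first sample included). Demanding literally every
sample above threshold rejects or grossly delays genuine bursts,
because the envelope of band-limited noise dips briefly below any
threshold even inside a sustained burst; a 50 ms burst still fails the
criterion. Arbitration returns the AGLR onset when the two detectors
agree within 20 ms and the fallback result flagged for review
otherwise; an AGLR alarm never confirmed by the sustained criterion is
treated as a false positive (no onset, flagged), as visual inspection
would. All overrides are logged.

H-reflex latency is the first time after blanking the stimulus artifact
(5 ms) at which the trace deviates from the pre-stimulus baseline by
more than 3 SDs sustained for 2 ms, searched in 15–50 ms.

## Numerical and statistical choices

- Band-pass: order-4 Butterworth, forward-backward (`sosfiltfilt`), so
  the filter contributes zero phase delay to onset times.
- Sliding RMS evaluated at every sample (the strictest reading of the
  rejection rule); one contaminated muscle rejects the whole trial.
- Angles interpolated linearly between samples (error ≤ 0.15° at
  291 °/s and 2 kHz); median with the midpoint convention; regression
  refused (subject excluded) when any required velocity lacks a median,
  never silently fitted on fewer points.
- Zero-variance medians: slope 0, R² reported as 0 with a degeneracy
  flag (the class is near_zero regardless).
- |slope| < 0.01 deg/(deg/s) classifies velocity independence: over
  55–291 °/s it bounds the threshold change by 2.36°, within natural
  within-subject variability (≤ 2.5°).
- Paired comparisons route by Shapiro–Wilk on the differences
  (α = 0.05) to the paired t-test or Wilcoxon signed-rank; an all-zero
  difference vector is reported as p = 1 with zero effect rather than
  an exception. Hedges' g uses the pooled-SD form with the
  1 − 3/(4·df − 1) small-sample correction. The Friedman omnibus
  (p = 1 on constant rows) gates six pairwise Wilcoxon contrasts with
  Bonferroni multiplication; standard test internals delegate to
  scipy.stats.

## Problem sizes

The stochastic demonstrations use 100 subjects for threshold recovery
and 200 cohorts of n = 12 for the velocity-effect pattern — large
enough that ≥90% pass rates are separated from their observed ~94–100%
by several binomial SDs, and small enough to run in minutes on one
core.

## Known limitations

- The detector operates on the model's Gaussian variance-burst EMG; on
  real recordings with slow artifacts or non-Gaussian bursts the
  false-alarm calibration does not transfer automatically.
- TSRT extrapolates a 4-point regression; R² and n_velocities are
  reported so users can judge extrapolation validity, and on corrected
  (velocity-independent) data the regression itself loses meaning —
  which is precisely the package's point.
- The H-reflex pathway underestimation (≤15% of ℓ) is bounded, not
  corrected.
- Inter-trial carry-over (post-activation depression) is not modelled;
  trials are statistically independent.
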