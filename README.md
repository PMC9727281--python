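# srtkit

Latency-corrected **stretch reflex threshold** (SRT) analysis for
passive-stretch dynamometry with surface EMG.

## The problem

Stretch hyperreflexia — an exaggerated stretch reflex (SR), the neural,
velocity-dependent component of hyper-resistance in conditions such as
spastic cerebral palsy — is quantified by the *stretch reflex
threshold*: the joint angle at which reflex EMG activity appears during
a passive stretch. The catch is that EMG onset lags the mechanical
reflex initiation at the muscle spindles by the monosynaptic latency
ℓ ≈ 28 ms. At stretch velocity *v* the uncorrected threshold is
therefore displaced ℓ·*v* degrees later into the stretch — 1.5° at
55 °/s, but 9° at 300 °/s. That systematic, velocity-proportional error
contaminates the SRT-velocity regression and the *tonic stretch reflex
threshold* (TSRT), its extrapolated zero-velocity intercept.

`srtkit` implements the correction

```
SRT           = θ(t_onset)
SRT_corrected = θ(t_onset − ℓ)
```

with ℓ measured per subject and muscle as the H-reflex latency (the
time from tibial-nerve stimulus to the initial EMG deflection), and
carries the analysis from raw trials to group statistics:

1. **synth** — synthetic dynamometer datasets with known ground truth:
   constant-velocity dorsiflexion ramps 20° → 0° at 55/110/210/291 °/s
   (20–40 ms acceleration), band-limited Gaussian background EMG,
   variance-burst reflex responses one latency after the true threshold
   crossing, stimulus-locked H-reflex traces, optional pre-stretch
   contamination.
2. **signal** — zero-phase 20–195 Hz band-pass; rejection of trials
   whose pre-stretch EMG RMS (200 ms sliding window, 500 ms interval)
   exceeds 5% of the maximal-voluntary-contraction RMS.
3. **onset** — SR EMG onset by an approximated generalized likelihood
   ratio (AGLR) variance-change detector with ML change-point
   refinement; a sustained-amplitude fallback (2 baseline SDs held
   ≥100 ms) and automated arbitration; H-reflex latency estimation.
4. **srt** — per-trial SRT/SRT_corrected, per-velocity medians, the
   SRT-vs-velocity ordinary least squares (velocity on x, TSRT =
   y-intercept), and velocity-dependence classification (|slope| < 0.01
   ⇒ velocity-independent).
5. **stats** — paired method comparisons routed by Shapiro–Wilk to a
   paired t-test or Wilcoxon signed-rank, Hedges' g, and the Friedman
   velocity-effect test with Bonferroni-corrected post-hoc contrasts.
6. **cli** — `srtkit simulate / analyze / report`.

## Worked example

```bash
cat > sim.yaml <<EOF
n_subjects: 12
rng_seed: 5
EOF
srtkit simulate --config sim.yaml --out data/
srtkit analyze --manifest data/manifest.csv --out results/
srtkit report --results results/
```

The report (abridged; simulated cohort, true threshold 19°, latency
~28 ms) prints per-velocity median (IQR) thresholds and regression
summaries:

```
Median (IQR) SRT by stretch velocity
  sol SRT               55 deg/s:   17.6 (0.3) deg
  sol SRT_corrected     55 deg/s:   19.1 (0.1) deg
  sol SRT              110 deg/s:   15.9 (0.4) deg
  sol SRT_corrected    110 deg/s:   19.0 (0.1) deg
  sol SRT              210 deg/s:   13.7 (0.9) deg
  sol SRT_corrected    210 deg/s:   19.1 (0.2) deg
  sol SRT              291 deg/s:   11.9 (1.3) deg
  sol SRT_corrected    291 deg/s:   19.0 (0.2) deg
Velocity regression summaries (median across subjects)
  sol corrected slope=-0.0002 R2=0.13 TSRT=19.1 deg
  sol original  slope=-0.0233 R2=0.99 TSRT=18.7 deg
```
(the `mg` rows, omitted here, behave the same)

Reading it: uncorrected thresholds drift to later angles as velocity
grows (slope ≈ −ℓ), exactly the latency artifact; corrected thresholds
sit at the true 19° at every velocity, the slope collapses to ~0 (and
with it the R² that made the regression look meaningful), while the
TSRT intercept barely moves.

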