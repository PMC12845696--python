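# Methods

This note documents the models, parameters, and design choices behind the
`stridefatigue` pipeline: what each stage computes, what the synthetic
cohort generator does and does not emulate, and where numerical conventions
were chosen because the underlying methodology leaves them open.

## Problem setting

A single lumbar-mounted IMU records tri-axial acceleration (ax, ay, az) and
angular velocity (gx, gy, gz) at 256 Hz while a runner completes two 400 m
segments: one non-fatigued (NF) and one after an exhaustive shuttle-run
protocol (F). Each stride becomes a labeled observation. The pipeline asks
three questions at increasing levels of personalization: does fatigue shift
stride biomechanics at the population level (mixed-effects inference); can a
pooled classifier recognize fatigue in an unseen runner (leave-one-
participant-out, LOPO); and can fatigue be detected within a runner, with
labels (personal supervised CV) or from a non-fatigued baseline alone
(One-Class SVM novelty detection)?

## Preprocessing and stride representation

- **Filtering.** Fourth-order Butterworth low-pass at 20 Hz, applied
  forward-backward (zero-phase) so foot-strike timing is not lag-shifted.
  The phase convention is a package choice; filter family, order, and
  cutoff follow the study design. The effective magnitude response is the
  squared single-pass response. Note that at 256 Hz sampling the digital
  (bilinear) design attenuates *more* than the analog formula above ~50 Hz
  because of frequency warping; the analytic-response test therefore runs
  at 4096 Hz where warping is negligible.
- **Derived channels.** amag = ||(ax, ay, az)||₂ and gmag = ||(gx, gy, gz)||₂
  per sample, computed *after* filtering the six raw channels (the order is
  a package choice; filtering first keeps the magnitudes consistent with
  the filtered axes).
- **Foot strikes.** Peaks of the filtered vertical acceleration with a
  minimum separation of 0.25 s (half the period of a 2 Hz maximum stride
  frequency) and a prominence of 0.5 × the channel's standard deviation.
  Both thresholds are configurable; they are detector policy, not data.
- **Strides.** Half-open windows between consecutive foot strikes (strides
  are disjoint and exhaustive between first and last event), linearly
  interpolated onto N = 128 equispaced phase points. N is a package choice
  (a power of two for FFT convenience); the stride's source duration Tᵢ is
  retained so spectral features can use the physically meaningful effective
  rate N/Tᵢ. One detected-event interval is treated as one stride
  throughout; whether that corresponds to one or two ground contacts does
  not affect any downstream contract.

## Features

Per channel and stride: mean, std, RMS, min, max, skewness, kurtosis and
energy — population (1/N) moments, non-excess kurtosis (Gaussian → 3),
energy = Σx². Eight channels × eight statistics give the 64-column base
matrix; "energy" is defined here as the sum of squared samples (the name is
conventional, the definition is not fixed elsewhere). Zero-variance strides
return skew = kurt = 0 with a degenerate flag instead of failing, so one
flat stride cannot abort a cohort run.

Spectral extensions per channel: dominant frequency, spectral entropy, and
bandpowers over [0.5, 3), [3, 8) and [8, 20) Hz (locomotor, impact,
high-frequency; configurable). The DC bin is excluded so the stride mean
does not masquerade as periodicity. Spectral entropy is the Shannon entropy
of the normalized one-sided power spectrum in nats, unnormalized by ln K.

Sample entropy uses the standard template-matching estimator: m = 2,
tolerance r = 0.2 × series SD (field-standard defaults), Chebyshev distance
with a ≤ comparison, ordered template pairs (i ≠ j), both the m and m+1
counts restricted to the n−m templates that admit an extension. A zero
match count returns NaN ("incomputable"), never ±∞. The implementation is
O(n²) vectorized; a brute-force oracle in the test suite checks exact count
agreement on all short series.

## Mixed-effects inference and effect sizes

Per feature y: y_ij = β₀ + β₁·Fatigue_ij + u_0j + ε_ij with participant
random intercepts u_0j ~ N(0, σᵤ²), fitted by REML (statsmodels MixedLM).
Unequal per-participant stride counts are handled by the hierarchical
structure. Effect sizes:

- Cohen's d = |β̂₁| / σ̂ (residual SD), reported as a magnitude;
- marginal / conditional R² (Nakagawa–Schielzeth) with σ²_fixed taken as
  the variance of the fixed-effect predictor over the observed design;
- partial R² = z² / (z² + df) from the Wald statistic of the fatigue term.

df is set to the total number of strides in the model by default. This is
an approximation to the effective residual degrees of freedom; with
stride counts in the thousands the value is insensitive to ±20 df. One
published worked example (the lateral-acceleration peak feature) prints a
partial R² one unit in the third decimal below what its printed z gives
under this formula — an upstream rounding; the formula value is kept.
Features are analyzed on their raw scale so coefficients stay in feature
units.

## Classification protocols

- **Global (LOPO).** One fold per participant; the test fold is that
  runner's entire stride set. Standardization statistics come from the
  train fold only (leakage is tested by spying on every fit call). Models:
  random forest (300 trees), RBF-SVM (C = 1, bandwidth from the median
  pairwise distance of up to 200 standardized train rows), gradient
  boosting (200 stages, learning rate 0.1); hyperparameters are seeded
  package defaults, all configurable. The cohort metric is the arithmetic
  mean of per-participant metrics, never stride-pooled accuracy. An
  optional shallow 1D-CNN stage on raw stride tensors is defined but
  requires torch; without it the stage disables itself cleanly and the
  pipeline proceeds.
- **Personal supervised.** Per runner: stratified K-fold (K = 5 default,
  reduced with a warning when a class is small, floor 2) random forest on
  that runner's strides only; fold-train standardization.
- **NF-only anomaly detection.** Per runner: One-Class SVM (RBF, ν = 0.1,
  bandwidth 1/(p·variance), i.e. the "scale" heuristic) fitted on the
  runner's NF strides standardized by NF-only statistics; at least 20 NF
  strides are required for a stable baseline. Every stride is then scored;
  the binary view uses the boundary's native zero level (ν makes this
  roughly a 10%-FPR operating point), and the AUC ranks the continuous
  anomaly scores with "more anomalous = more fatigue-like" orientation.
  ν = 0.1 matches the roughly 10% NF false-positive rate the protocol is
  designed around.

AUC is computed by the rank (Mann–Whitney) formulation with ties counted ½.

## Stride-to-stride variability

For a feature tracked across the ordered strides of one run: mean,
population variance, CV = σ_f/μ_f, and trajectory sample entropy (same
m = 2, r = 0.2σ defaults) of the stride-ordered sequence. Deltas are exact
F − NF differences per runner and feature. Trajectories never cross the
NF/F boundary. Default feature list: acc_mag_rms and gyro_mag_rms
(configurable).

## Synthetic cohort generator

The generator exists so every downstream stage is testable without the
on-request field dataset. It emulates the *structure* of that dataset — 19
runners, two labeled 400 m segments each, 50–80 strides per segment at
256 Hz, participant-level baseline offsets, and fatigue effects with the
documented directions — in arbitrary m/s²-like and deg/s-like units.

Signal model per channel: DC offset plus three harmonics of the stride
frequency (participant-specific, ~1.3 ± 0.08 Hz); the vertical channel adds
one Gaussian impact pulse per stride at foot strike (amplitude 8, width
0.05 s). Stride periods are jittered (SD 2% of the period), white
measurement noise (SD 0.3) is added to every channel, and each participant
draws a random intercept (SD 1.0) added to every channel's DC level.

Stride-to-stride structure: the oscillatory content of each stride is
scaled by a gain 1 + drift + noise, where the drift is a slow sinusoid over
stride index (amplitude 0.3, period 20 strides — a pacing-fluctuation
surrogate) and the noise is white per-stride force variability (SD 0.08).
These two components are what give feature trajectories realistic
autocorrelation and a non-fatigued acc_mag_rms CV of ≈ 0.03, the scale
reported for real runners.

Fatigue (F segments) applies: vertical DC −0.8 (propulsion down); +1.5 on
the fundamental lateral amplitude (peaks up); impact pulse sharpened ×1.5
area-preservingly (amplitude ×1.5, width ÷1.5), so kurtosis rises without
contaminating the configured vertical-mean delta; gyro amplitudes ×1.15
(rotational RMS up); measurement-noise SD ×1.5 and timing-jitter SD ×1.5
(irregularity up). At the trajectory level, fatigue attenuates the smooth
pacing drift by the jitter-inflation factor and converts the removed
variance into additional white per-stride variability ("structure becomes
noise"): total gain variability never decreases, so the CV rises, while the
trajectory whitens, so its sample entropy rises — the two variability
signatures reported for fatigued running. The rotational-gain dial exists
because noise inflation alone shifts gyro RMS by a negligible fraction of
its harmonic-dominated value and could not express the documented
"rotational RMS up" direction.

What the generator does **not** emulate: real impact transients and
ground-reaction dynamics, orientation drift, soft-tissue artifacts,
participant-specific *effect* heterogeneity (every runner gets the same
fatigue deltas; heterogeneity enters only through baselines), or any
physiological units. Passing tests on this cohort therefore demonstrate
that the pipeline recovers known effects under its stated noise model —
not that those effects hold in any real cohort.

## Determinism and numerical conventions

All randomness flows from a single integer seed per run
(`numpy.random.default_rng`); identical seed and configuration give
byte-identical output tables, which the test suite asserts end-to-end.
Stride windows must be finite; windows shorter than 4 samples are dropped
with a warning; segmentation failures (fewer than 2 events) flag the
recording and skip it rather than aborting the cohort. CSV is the only
output format; a JSON sidecar carries recording metadata.

## Problem sizes used in the test suite

The suite runs cohorts of 2–6 participants with 12–110 strides per
condition, chosen so each check exercises the regime it needs (e.g.,
trajectory entropy is estimated on 100+ stride trajectories where the
template counts are stable, while classifier contracts use small separable
cohorts). Mixed-model recovery uses direct draws from the random-intercept
model itself (20 participants × 200 strides; 40 null replicates for the
type-I check), which isolates the estimator from the signal pipeline. The
numbered analysis drivers run the full 19-runner, 50–80-stride default
configuration.

## Known limitations

- Foot-strike detection assumes an impact-dominated vertical channel;
  heavily smoothed or atypical waveforms may need the prominence and
  separation parameters adjusted.
- Sample entropy is O(n²) in series length; fine at N = 128 and for
  trajectories, but not intended for multi-minute raw series.
- The df convention in the partial R² is an approximation by design; exact
  Satterthwaite-style degrees of freedom are out of scope.
- The One-Class SVM's binary operating point is the native zero level; no
  per-runner threshold optimization is performed.
- No multiple-testing correction is applied across features, matching the
  reporting convention of the study design this follows.
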