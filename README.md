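# stridefatigue

Detecting running fatigue from a single lumbar-mounted IMU, stride by
stride. The package implements a complete analysis pipeline for the
two-run protocol used in wearable fatigue studies — a non-fatigued (NF)
400 m run, an exhaustive shuttle-run protocol, then a fatigued (F) 400 m
run — and asks, at three levels of personalization, how fatigue changes
stride biomechanics and whether it can be detected automatically.

It is written for researchers in wearable-sensor biomechanics and
physiological time-series analysis who want a tested, reproducible
implementation of this analysis chain, including a synthetic cohort
generator so that every stage runs and is verifiable without access to
the (on-request) field dataset.

## What it computes

Starting from multichannel recordings `(ax, ay, az, gx, gy, gz)` at
256 Hz:

1. **Stride segmentation** — 4th-order zero-phase Butterworth low-pass
   (20 Hz), derived magnitude channels `amag = √(ax²+ay²+az²)` and
   `gmag = √(gx²+gy²+gz²)`, foot-strike detection as prominent peaks in
   vertical acceleration, and time normalization of each stride
   `sᵢ ∈ ℝ^(N×8)` to N = 128 points.
2. **Features** — per channel: mean, σ, RMS, min, max, skewness γ,
   kurtosis κ, energy (the 64-column base matrix), plus dominant
   frequency, spectral entropy `H = −Σ pₖ ln pₖ`, bandpowers, and sample
   entropy `SampEn(m, r) = −ln(A/B)`.
3. **Mixed-effects inference** — per feature, a REML fit of
   `y_ij = β₀ + β₁·Fatigue_ij + u_0j + ε_ij` with participant random
   intercepts, plus standardized effect sizes: Cohen's d = |β̂₁|/σ̂,
   Nakagawa–Schielzeth marginal/conditional R², and the partial R² of the
   fatigue term, `R² = z²/(z² + df)`.
4. **Global classification** — random forest, RBF-SVM and gradient
   boosting under strict leave-one-participant-out (LOPO) evaluation.
5. **Personalized detection** — per-runner supervised random forests
   (stratified K-fold) and NF-only One-Class SVM novelty detection, which
   flags fatigued strides as deviations from the runner's own baseline.
6. **Stride-to-stride variability** — per runner × state × feature: CV =
   σ_f/μ_f and trajectory sample entropy, with exact F − NF deltas.

See `docs/methods.md` for the model details, parameter defaults, and what
the synthetic generator does and does not emulate.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (19 runners, 50–80 strides per condition, seeded):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_segment_and_features.py
python analysis/03_fatigue_effect_sizes.py
```

which prints

```
feature table: 2297 strides (1167 NF, 1130 F), 112 features
     feature  beta_fatigue       z  cohen_d  r2_partial
acc_mag_kurt         3.041 120.261    5.034       0.863
  acc_z_mean        -0.788 -72.372    3.030       0.695
   acc_y_max         1.382  72.047    3.016       0.693
  gyro_y_rms         5.000  16.031    0.670       0.101
```

Every configured fatigue direction is recovered: vertical acceleration
mean down (the generated truth is −0.8; the model estimates −0.788 with
|z| = 72), impact kurtosis, lateral peaks and rotational RMS up, all with
the participant intercept absorbed by the random effect. Continuing,

```sh
python analysis/05_personal_models.py
python analysis/06_stride_variability.py
python analysis/07_heterogeneity_gap.py
```

reports mean personalized-RF accuracy 0.9996 (AUC 1.0000) and NF-only
One-Class SVM recall 1.0000 at FPR 0.1634 on this cohort; cohort-median
variability deltas ΔCV = +0.0065 and ΔSampEn = +0.3203 for `acc_mag_rms`
(fatigue makes stride trajectories both more variable and less regular);
and, on a heterogeneity-dominated cohort where between-runner baseline
differences dwarf the fatigue shift,

```
mean LOPO accuracy 0.621 (per-runner range 0.39-0.99) vs
mean within-runner CV accuracy 0.920
```

— the central contrast of this analysis: population-level fatigue models
transfer poorly to unseen runners, while personalized models remain
accurate. (The default cohort applies identical fatigue deltas to every
runner, so LOPO models generalize perfectly there; the gap appears exactly
when runner heterogeneity dominates, as it does in real cohorts.)

The same stages are available as a CLI over YAML configs:

```sh
stridefatigue run --config config.yaml --seed 1 --out results/run1
stridefatigue simulate --config config.yaml   # stages compose one by one
```

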