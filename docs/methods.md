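# Methods

This note documents the statistical and numerical choices behind
`ehgterm`: what each pipeline stage computes, which parameters are fixed
and why, what the synthetic cohort generator does and does not emulate,
and the package's known limitations.

## Problem setting

The package predicts preterm birth — delivery before 259 days (37
completed weeks) of gestation — from two information sources recorded
during routine check-ups:

* a single-channel electrohysterogram (EHG): the uterus's electrical
  activity measured by surface electrodes on the maternal abdomen, a
  roughly 30-minute trace sampled at 20 Hz;
* a table of clinical covariates (maternal age, weight, parity, prior
  abortions, first/second-trimester bleeding, hypertension, diabetes,
  placental position, smoking) with substantial missingness.

Cohorts are small (order 10² mothers) and imbalanced (roughly 19%
preterm), which drives most of the methodology below: class-weighted
losses, stratified resampling, prevalence-aware operating points, and
strict fold-scoping of every data-dependent statistic.

## Signal conditioning

`condition_signal` (module `signal_spectral`):

1. discard the first 60 s (electrode settling transients);
2. band-pass 0.05–4 Hz with a 4th-order Butterworth filter applied
   forward and backward (`scipy.signal.filtfilt`), so the net phase is
   zero and the effective magnitude response is the squared single-pass
   response;
3. decimate from 20 Hz to 10 Hz by integer stride. No extra
   anti-aliasing stage is needed because the 4 Hz band edge is already
   below the post-decimation Nyquist frequency of 5 Hz.

The passband is wide enough for uterine contractile activity
(≤ ~1 Hz) and the maternal-cardiac interference band (~1–4 Hz), and
excludes baseline wander below 0.05 Hz.

## Spectral features

`compute_stft` slides a 60 s Hamming window with 75% overlap (hop 15 s)
over the conditioned 10 Hz trace and keeps the one-sided magnitude
spectrum per frame, transformed as `log(1 + |X|)`. A 30-minute
recording yields a 301×113 frequency-by-time matrix with 1/60 Hz
frequency spacing. The 60 s window trades frequency resolution against
the ability to localize individual contractions; the log transform
compresses the dynamic range (contraction bursts are an order of
magnitude stronger than the harmonics) while mapping zero signal to
exactly zero.

## Models

### EHG sequence model

The STFT columns are fed as a length-113 sequence of 301-dimensional
steps into a bidirectional LSTM (default 100 hidden units per
direction). The terminal hidden state of each direction is concatenated
and mapped by a 2-unit fully connected layer to either

* a softmax over {term, preterm} for classification, trained with the
  class-weighted cross-entropy

  `L = -(1/N) Σ_n [ w₁ T_n ln y_n + w₀ (1-T_n) ln(1-y_n) ]`,

  with weights `w_i = 2 S_{1-i} / (S₀ + S₁)` from the *training-fold*
  class counts (so the weights always sum to 2 and the minority class is
  upweighted; at counts 129 term / 30 preterm, w₁ ≈ 1.623 and
  w₀ ≈ 0.377), or
* a linear unit for regression on gestational age at delivery, trained
  with mean squared error on targets centered at 280 days and scaled by
  20 days.

The network is implemented directly in numpy (forward and
backward-through-time passes, Adam updates, global-norm gradient
clipping at 1.0, L2 of 1e-4 on weight matrices only, forget-gate biases
initialized to 1, Glorot-uniform weight initialization). The analytic
gradients are validated against finite differences to ~1e-6 in the test
suite. Per-frequency z-scoring statistics for the input are computed on
training rows only.

Unreported-in-advance hyperparameters are fixed at: batch 16, 60
epochs, Adam step 1e-3. All are overridable through `TrainConfig`;
tests and the acceptance script use smaller networks and fewer epochs
(see "Reduced problem sizes" below).

### Clinical models

Covariates are preprocessed fold-scoped (`clinical_preprocess`): every
variable, including continuous ones, is imputed by the training-fold
mode (ties broken toward the smallest value), and — on the
classification path only — z-scored with training-fold statistics.
Classification uses L1-penalized logistic regression with the penalty
chosen by inner stratified 5-fold held-out deviance over a grid
`λ ∈ logspace(-2, 2, 13)`; regression uses ordinary least squares on
raw imputed features (only the classification model is regularized).
Cervical-length-style sonographic variables (funneling) are excluded as
predictors.

The lasso solver is a hand-rolled IRLS + cyclic coordinate-descent
routine (objective `Σ logloss + λ‖w‖₁`, intercept unpenalized). This
choice is deliberate: proximal/stochastic solvers split weight
symmetrically across duplicated columns and do not recover the
intercept-only solution under extreme penalties, whereas coordinate
descent drives coefficients exactly to zero, so the two defining
properties of the method — redundant predictors are discarded, and an
infinite penalty degenerates to predicting the training prevalence —
hold exactly.

### Combined model

For each training fold, the sequence network is trained on that fold,
the 2-unit fully connected activations are extracted for all rows, the
training-fold activations are z-scored with training statistics, and
the clinical feature matrix is concatenated with the 2 activations.
The combined matrix is fit by the lasso-logistic (classification) or
OLS (regression) head. Note an inherent property of this stacking
design: training-fold activations come from a network that saw those
rows' labels, so they are partially memorized; the inner CV for λ can
therefore overweight them when the EHG carries no real signal. This
does not bias held-out evaluation (test-fold activations are genuinely
out-of-sample) but it does shrink the combined model's margin over the
EHG model when the only true signal is clinical.

## Evaluation

`repeated_cv` runs stratified 5-fold cross-validation repeated 20 times
under one master seed. Stratification assigns each class to folds
round-robin after a class-wise shuffle, with the round-robin start
staggered between classes so per-fold totals stay balanced; per-fold
preterm counts differ by at most one. Every data-dependent statistic —
imputation modes, scaling, penalty selection, network training — is
computed inside the training fold only.

Each repeat's five test folds are pooled into a single score vector
yielding one AUC per repeat (per-fold AUCs on ~6 positives would be too
unstable); the report is the mean over 20 repeats with a t-based 95% CI
(Student t, 19 df). AUC is the Mann–Whitney statistic with ties counted
one half. Single-sample AUC CIs use the Hanley–McNeil standard error on
the logit scale, back-transformed so limits stay inside (0, 1);
degenerate AUCs of exactly 0 or 1 are pulled in by half a Mann–Whitney
step before the transform, with a warning.

Operating points: sensitivity at specificity 50/70/90% is read off the
ROC by linear interpolation between adjacent vertices; PPV and NPV are
computed from the prevalence identity
`PPV = sens·π / (sens·π + (1-spec)(1-π))`,
`NPV = spec(1-π) / (spec(1-π) + (1-sens)π)` with π the sample
prevalence. Risk ratios between covariate arms carry log-scale normal
CIs with no continuity correction (zero event cells raise instead).

### Label-noise AUC ceiling

Gestational age itself is dated with roughly ±6-day uncertainty, which
caps any classifier's achievable AUC. `label_noise_auc_bound` scores
each subject by the negated noisy delivery age `-(ga + ε)`,
`ε ~ N(0, sd²)`, against the true 259-day label, and reports the mean
AUC over 20 draws with its t-CI. With sd = 0 the bound is exactly 1;
with sd = 6 days on a realistic gestational-age mixture it sits near
0.97–0.99.

## Perturbation experiments

Three information-loss experiments on the STFT, applied identically to
training and test data, localize where the predictive signal lives:

* **band extraction** — keep only rows in one of B0 [0.05, 1.0),
  B1 [1.0, 2.2), B2 [2.2, 3.5), B3 [3.5, 5.0] Hz (B0 contains mostly
  contractile activity, the upper bands maternal-cardiac harmonics);
* **column shuffling** — permute ⌈f·T⌉ randomly chosen columns among
  themselves, destroying temporal ordering while preserving every
  column's spectrum;
* **cropping** — keep a contiguous block of columns equivalent to a
  shorter recording, with a per-sample random start.

Each perturbed cohort runs through the same repeated CV of the EHG
classifier; the output is mean AUC with CI per grid point.

## Synthetic cohort generator

Real cohorts of this kind cannot be redistributed, so every stage is
exercised against `synthetic_cohort`, which generates cohorts with the
statistical structure the analysis assumes:

* **outcomes** — preterm with configurable prevalence; gestational age
  at delivery from a mixture (term: normal(280, 9) truncated at 259;
  preterm: triangular on [189, 258] with mode at the upper edge);
* **signals** — sum of integrated-noise baseline wander (< 0.05 Hz),
  Poisson-arriving (mean 4/30 min) contraction bursts (~60 s Hann
  envelopes modulating 0.1–0.7 Hz band-limited noise), quasi-periodic
  cardiac-harmonic tones near 1.3/2.6/3.9 Hz with phase jitter, and
  white noise;
* **class effects** — `spectral_effect` multiplies preterm power in the
  1.0–3.5 Hz components by (1 + effect); `clinical_effect` multiplies
  the odds of smoking and second-trimester bleeding for preterm
  mothers. With both at their null values the joint (signal, covariate)
  distribution is identical across classes — the basis of the
  anti-leakage calibration tests;
* **missingness** — per-variable masking at rates matched to a
  realistic cohort (13–19% on most maskable variables).

The generator is a testing instrument, not a biophysical model: it
reproduces band-power structure, arrival statistics, and
covariate-outcome associations, but not waveform morphology,
electrode-placement effects, inter-channel structure, or any real
physiological coupling between the clinical covariates and the signal.

## Reduced problem sizes

The default configuration (hidden 100, 60 epochs, 20×5 CV) matches the
full analysis but is far too slow for a test suite on one CPU. Tests
and the acceptance script therefore run deliberately reduced settings —
hidden 8–16 units, 3–15 epochs, cohorts of 60–160 mothers, 3–20
repeats — chosen so that each asserted effect is comfortably larger
than its measured estimation noise. These sizes are package choices;
nothing in the API depends on them.

## Limitations

* The numpy network is CPU-bound and small-scale; it is not intended
  for architecture exploration.
* Statistical power at test sizes is finite: property tests assert
  directions and calibrated intervals, not headline effect sizes.
* The WFDB reader covers the subset of the format needed here (format
  16, single channel, key-value comment metadata).
* PPV/NPV are computed from the prevalence identity, so they inherit
  the sample prevalence; they are not transportable to populations with
  different base rates without re-weighting.
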