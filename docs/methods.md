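# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `sleepfusion`.  It is written for users who want to
know what the pipeline computes, why the defaults are what they are, and
what passing the test suite does and does not demonstrate about clinical
data.

## Problem setting

REM sleep behavior disorder (RBD) degrades the reliability of automated
sleep staging: loss of REM atonia injects EMG-band activity into REM
epochs, nights are fragmented, and REM–wake boundaries blur.  The
package implements an EEG-only three-class (Wake/NREM/REM) stager built
for this regime, together with the two layers of downstream statistics a
clinical translation study needs: night-level stage-proportion agreement
against manual scoring, and associations between automated REM% (of
total sleep time) and symptom scales.

## Signal conditioning

The chain is fixed: band-pass -> wavelet denoise -> resample -> epoch ->
artifact QC, applied per channel, fully deterministic.

* **Band-pass** 0.5–35 Hz, 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`) for zero phase.  The 35 Hz edge also
  anti-aliases the later decimation to 100 Hz.
* **Wavelet denoising**: db4, 5 decomposition levels, soft thresholding
  of every detail level at the universal threshold `sigma*sqrt(2 ln N)`
  with `sigma = MAD(finest detail)/0.6745`.  On a noiseless smooth
  signal the MAD is ~0 and the step is a near-identity; on 5 dB-SNR
  input it strictly reduces RMSE to the clean signal (tested).
* **Resampling** to the 100 Hz model rate by polyphase filtering;
  upsampling is refused so the model never sees interpolated bandwidth.
* **Artifact QC** per 30-s epoch, any channel: |amplitude| > 500 µV,
  variance < 0.01 µV² (flatline), or power(>35 Hz)/power(0.5–35 Hz) >
  0.5 evaluated on the pre-filter signal (after filtering the ratio is
  trivially small).  Thresholds are config values, chosen as ordinary
  clinical-EEG screening limits.  Flagged epochs are excluded from
  training; during whole-night prediction they are staged anyway (with a
  warning) so hypnograms stay gap-free — removal-only is the one
  artifact action implemented.

## Per-epoch representations

Every conditioned 30-s epoch (8 channels x 3000 samples) yields three
views:

1. **Raw waveform**, standardized per epoch and channel.
2. **Spectrogram tensor** 8 x 32 x 32: per-channel STFT (128-sample Hann
   window, hop 32), magnitude-squared, `log10(power + 1e-10)`, rows
   restricted to 0.5–35 Hz, bilinear resize to 32 x 32, per-channel
   z-normalisation.  The log + z-norm makes the tensor invariant to
   overall amplitude scaling.
3. **65 handcrafted descriptors**: per channel `[mean, SD, RMS,
   rel_delta, rel_theta, rel_alpha, rel_beta, rel_lowgamma]` (8 x 8 =
   64) plus the channel-averaged 90% spectral edge frequency (SEF90).
   Band powers come from Welch PSDs (4-s Hann segments, 50% overlap,
   0.25 Hz resolution) relative to total 0.5–35 Hz power, so the five
   bands sum to one; SEF90 is the smallest PSD grid frequency at which
   the cumulative 0.5–35 Hz power reaches 90% (a discrete rule — no
   interpolation inside the crossing bin — so the value is always an
   actual grid frequency).  Degenerate epochs (total power < 1e-12 µV²)
   report zero band powers and SEF90 pinned to 0.5 Hz with a flag,
   never NaN.  The layout is versioned
   (`FEATURE_LAYOUT_VERSION`); variance is deliberately omitted as
   redundant with SD to keep the count at 65.

## Network

Three streams feed a gated fusion:

* 1D stream: three conv–batchnorm–ReLU–maxpool blocks
  (8->32->64->64 channels, kernels 7/5/3, first conv stride 3, pool 4)
  with global average pooling to a 64-d embedding.
* 2D stream: three 3x3 conv blocks (8->16->32->64, 2x2 pooling), global
  average pooling to 64-d.
* Handcrafted stream: the 65-d vector, z-scored with statistics
  estimated **on the development folds only** (no leakage).

Concatenation gives z in R^193 (64 + 64 + 65, asserted at construction).
A two-layer MLP (193->96->193) with sigmoid output produces a gate g in
(0,1)^193 and the classifier consumes `g ⊙ z` through dense layers
193->128->64->3 with dropout 0.5/0.3 and a softmax.  Argmax ties break
to the lowest class index.

The network is implemented on an in-repo numpy layer library with
hand-written backward passes (valid convolutions via im2col + BLAS
matmuls, batch norm, max pooling, dense, dropout) and an Adam optimizer.
Float32 is the compute dtype (the workload is memory-bandwidth bound);
the test suite re-runs every layer in float64 against central finite
differences at 1e-6 relative tolerance.

## Training and evaluation protocol

* Class-weighted cross-entropy, `w_c = N_total / (3 N_c)`; with unit
  weights the loss equals plain cross-entropy to machine precision
  (tested).
* Adam at 1e-3, batch 64, at most 30 epochs, reduce-on-plateau (factor
  0.5, patience 2) on validation loss, early stopping (patience 4) and
  model selection on validation **macro-F1**.  The short schedule is a
  deliberate choice: on the separable synthetic regime the model
  converges within a handful of epochs, and the cap keeps a full
  cross-validated run tractable on one desktop CPU.
* Inner validation split: 20% of development subjects (at least one),
  subject-wise.
* Patient-wise k-fold CV (k = 5): every epoch of a subject lives in
  exactly one test fold; training, early stopping and selection never
  see test subjects.  The fold assignment object re-validates this
  invariant on every run and the evaluation pools out-of-fold
  predictions across folds.
* For visualization-style reporting a class-balanced subset (n per
  class, seeded, without replacement) can be drawn from the pooled
  predictions; it reuses the same metric code path.

All randomness (init, shuffling, splits, dropout) descends from a single
seed; identical configs reproduce identical metrics.

## Night-level summaries and agreement

TST = 0.5 min x #(non-wake epochs); REM% = 100 x #REM / (#NREM + #REM);
NREM% = 100 − REM%.  A night with zero sleep epochs is flagged
(undefined percentages) rather than silently NaN.  Agreement between
automated and manual REM%/NREM% uses Bland–Altman (bias = mean of
automated − manual, limits = bias ± 1.96 x sample SD), MAE, and
ICC(A,1) — two-way model, absolute agreement, single measurement — with
the McGraw–Wong F-based 95% CI.  Because NREM% ≡ 100 − REM%, the NREM
report is the exact sign-mirror of the REM report; this identity is
asserted in tests.

## Association statistics

Spearman rho uses midranks and the t approximation (n − 2 df) for p;
BH-FDR is the step-up rule with the family defined as exactly the set of
correlations submitted in one call (the family is caller-defined and
logged, since different studies correct across different test sets).
Multivariable models are OLS with the outcome and continuous predictors
z-scored and binary covariates (sex, medication) left 0/1 — so reported
betas are standardized for continuous terms only, recorded in the result
metadata.  A rank-deficient design raises an error naming a removable
column, preferring covariates over the predictor of interest.
Collinearity aside, the regression is delegated to statsmodels; the
Spearman/FDR/ICC primitives are implemented here and cross-checked
against scipy, statsmodels and pingouin in the tests.

## Synthetic cohorts

The generator produces, from one master seed: Markov hypnograms, stage-
conditioned EEG, and clinical-scale tables.

* **Hypnograms**: first-order chain over Wake/NREM/REM with sticky
  states (self-transitions 0.90/0.91/0.85) — the reduced REM
  self-transition emulates RBD-like REM fragmentation.  No NREM
  substages, matching the three-class scope.
* **EEG**: each epoch is 1/f background (exponent 1, 10 µV RMS) plus
  band-limited Gaussian components synthesized by spectral shaping, with
  stage-specific RMS amplitudes — Wake alpha-dominant with a 2.5x
  occipital (O1/O2) gain, NREM delta-dominant with 11–15 Hz central
  spindle bursts, REM theta-dominant.  REM epochs additionally receive
  20–35 Hz bursts with probability 0.3 (the lost-atonia EMG-leak
  analogue); raising that probability strictly raises REM low-gamma
  power (tested).  Amplitudes are ordinary clinical magnitudes (tens of
  µV) and synthesis happens directly at the 100 Hz model rate by
  default; a higher native rate is available for I/O and resampling
  tests.
* **Scales**: score = intercept + slope x (REM% − 13) + Gaussian noise,
  rounded and clipped to instrument ranges (PSQI 0–21, ESS 0–24, RBDSQ
  0–13).  Slopes are derived from target rank correlations through the
  bivariate-normal identity rho_s = (6/pi) asin(r/2); defaults plant
  rho ~ −0.5 for PSQI, −0.45 for RBDSQ and 0 for ESS.  Demographics
  (age, sex, BMI, medication) are drawn to resemble a mid-60s RBD
  clinic cohort.

**What the generator does not emulate**: real EEG nonstationarity within
epochs, inter-subject spectral variability, electrode artifacts beyond
simple amplitude bursts, EOG/EMG crosstalk, medication effects, or any
genuine ambiguity at stage boundaries.  The synthetic classes are
linearly separable in feature space by construction (verified > 90% by a
logistic probe).  Consequently, near-perfect cross-validated F1 on
synthetic cohorts demonstrates that the pipeline, training loop and
evaluation plumbing are correct — it says nothing about clinical
accuracy, where published three-class performance in RBD sits near
F1 0.8–0.94 per class with errors concentrated at the REM–wake
boundary.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` runs the whole two-stage workflow at desk scale:
a 10-subject x 240-epoch development cohort for five-fold patient-wise
CV, a frozen refit on that cohort, an independent 44-subject x 60-epoch
application cohort for Bland–Altman/ICC agreement, and a 44-subject
association analysis with planted effects.  These sizes are the
package's chosen simulation conditions: large enough for stable
night-level statistics, small enough to run on a single CPU in minutes.

## Known limitations

* Three classes only; no N1/N2/N3 substaging, spindle/K-complex
  detection, or RSWA quantification.
* EDF writing supports the plain 16-bit EDF subset (integer rates, one
  1-s record block, µV units) — sufficient for round-tripping synthetic
  cohorts, not a general EDF+ writer.
* The numpy network trains on CPU only and is sized accordingly; the
  architecture hyperparameters (layer widths, gate width, dropout,
  schedule) are pinned package choices, not values fitted to any
  external dataset.
* Artifact *correction* is not implemented; flagged epochs are excluded
  (training) or staged with a warning (prediction).
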