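# Methods

## Overview

The package simulates a P300-speller aptitude study end to end: a cohort of
subjects with latent ERP parameters performs an RSVP oddball task and a 6×6
matrix-speller task; the RSVP yields five behavioral/ERP features per
subject, the speller a cross-validated single-trial classification AUC; and
regression models quantify how well the RSVP features predict the AUC. This
note documents the generative model, the measurement chain, the estimators,
the numerical choices, and what the synthetic setting can and cannot show.

## Synthetic cohort model

### Latent subject parameters

Each subject is a draw of six latent parameters: mean single-trial P300
amplitude `amp_mean` (μV) and latency `lat_mean` (ms), their trial-level
jitters `amp_sd` and `lat_sd`, the RSVP target-report probability `t1_prob`,
and the background-noise SD `noise_sd` (μV at unit-gain channels).
Population means/SDs default to the study's reported cohort statistics:
amplitude 2.88 ± 0.92 μV, latency 455.8 ± 65.6 ms, T1% 91.87 ± 5.7,
amplitude trial variation 1.88 ± 0.41 μV.

Two latent defaults are *not* copied from reported numbers, deliberately:

* **Latency jitter (60 ± 10 ms).** The reported trial variation in latency
  (251.2 ± 26.6 ms) is dominated by single-trial measurement scatter — an
  argmax over a 250–750 ms window driven by noise is nearly uniform, capping
  the attainable SD near 144 ms — so it cannot be read back as a latent
  jitter. 60 ms is a physiologically plausible latent value; the measured
  trial variation then lands in the 100–150 ms range once peak-picking
  scatter is added, with between-subject spread set by the calibration
  below.
* **Noise level (6 ± 1.5 μV).** Calibrated once so that the simulated
  cohort's mean 10-fold speller AUC falls near the reported 0.84 (it
  measures 0.83 at the acceptance-script problem size). The level also sets
  the upward bias of the measured amplitude; the cohort mean measured
  amplitude lands at ~2.7 μV against the latent 2.88 μV.

Latent parameters are coupled through a one-factor model: an
attentional-stability factor `z ~ N(0,1)` per subject with loadings +0.7 on
amplitude and detection probability, −0.3 on latency, −0.35 on latency
jitter and −0.2 on noise; amplitude jitter correlates 0.61 with amplitude
(the study's reported value). Fully independent draws were rejected during
design: they make T1% carry no performance information at all, contradicting
the reported T1%–AUC correlation (r ≈ 0.36), and leave latency variation as
the only informative feature. The loadings were calibrated so the emergent
cross-subject feature–AUC correlations approximate the reported ones
(measured over 20 simulated cohorts: T1% 0.23, amplitude 0.30, latency
variation −0.57). `PopulationSpec.coupling = 0` restores independent draws.

### Signal synthesis

* **Evoked response**: a Gaussian bump (default FWHM 100 ms, zero outside
  ±3 FWHM), peaking at the per-trial latency with per-trial amplitude drawn
  from the subject's truncated-normal amplitude distribution. Only target
  stimuli evoke it; non-targets are noise. Latencies are clipped to
  [50, 780] ms so the peak stays inside the 800 ms epoch.
* **Background noise**: equal-variance sum of an AR(1) process (coefficient
  0.95) and white noise, scaled to `noise_sd` — a 1/f-weighted spectrum
  typical of EEG without extra dependencies.
* **Spatial profile**: a fixed gain vector over the 32-channel montage,
  1.0 at Cz/Pz/CP1/CP2 decaying to 0.3 at the frontal/occipital rim,
  applied to both the evoked template and the noise. The injected template
  is additionally rescaled so that, after common-average referencing, the
  channel-averaged (Fz/Cz/Pz/CP1/CP2) peak equals the latent amplitude —
  without this, CAR would attenuate the injection by (gain − mean gain) and
  the latent parameter would no longer be on the scale of its measured
  analogue.
* **Paradigm timing**: RSVP streams of 21 letters at 10 Hz, one target per
  trial uniform over stream positions 5–17 (1-based), 40 trials; speller
  sequences of 12 row/column flashes at 187.5 ms SOA (125 ms flash + 62.5 ms
  ISI), 15 repetitions per character, calibration words BRAIN/POWER and test
  words SUBJECT/NEURONS/IMAGINE/QUALITY. Event-count identities (one target
  per stream; 2 target flashes per sequence; 30 target/150 non-target
  flashes per character; 840/4,200 epochs over four 7-letter words) hold for
  any seed.
* **Behavior**: each RSVP trial is reported correctly with probability
  `t1_prob`; wrong trials split evenly between a wrong key press and a
  non-response, both counted as errors by T1%.
* **Randomness**: everything flows from one integer seed through spawned
  `SeedSequence` streams (cohort → subject → session/fold), so a config plus
  seed reproduces every output bit-identically.

## Measurement chain

Preprocessing follows the fixed order CAR → band-pass → epoch → reject →
(RSVP only) drop adjacent non-targets; all steps are pure functions.

* **Filter**: 4th-order Butterworth band-pass 0.5–10 Hz applied
  forward-backward (`sosfiltfilt`), chosen zero-phase because filter group
  delay would otherwise shift ERP latencies — the effective magnitude
  response is the squared Butterworth response.
* **Epochs**: [0, 800) ms post-onset, half-open sample windows
  (floor(0.8·rate) samples, onset sample included; 409 at 512 Hz), baseline
  mean over [−200, 0) ms subtracted per epoch and channel. Events too close
  to a recording edge are dropped with a warning.
* **Artifact rejection**: an epoch is rejected if any channel's peak
  absolute amplitude exceeds 100 μV, or deviates from the across-trial mean
  of peak amplitudes by more than 5 SD. The mean/SD are computed
  leave-one-out (over the other epochs): with the tested epoch included, the
  largest attainable deviation at n epochs is (n−1)/√n SD — below 5 for any
  n < 27 — so a single extreme epoch would always mask itself and the rule
  would never fire at these trial counts.
* **Adjacent non-targets**: at a 10 Hz presentation rate the epochs of the
  non-targets following a target still contain the target-evoked response,
  so the k = 3 following stream positions are excluded. "Adjacent" was
  interpreted as *following* (preceding non-target epochs end before the
  target response develops).
* **Ocular artifacts**: the ICA-based correction used on real recordings is
  a pass-through hook here; the generator produces no ocular artifacts, and
  a real-data adapter can plug into `ica_artifact_hook`.

### Features

Peak measures use the per-trial definition throughout: on each retained
target epoch's channel-averaged waveform, latency is the time of the maximum
sample in 250–750 ms (earliest sample on ties — deterministic and
order-independent) and amplitude is the mean over ±50 ms around that peak,
clipped at epoch edges. X2/X3 are the means and X4/X5 the sample SDs (n−1)
of the same per-trial series — one consistent estimator for level and
variation; the alternative (peak of the trial-averaged waveform) would not
support the variation features. Trial-count restrictions ("first N trials")
use the first min(N, retained) retained trials, since rejection leaves
different trials per subject. At least 5 retained trials are required for
the SD features.

## Classifier

Speller epochs are decimated by averaging non-overlapping 24-sample blocks
(409 → 17 at 512 Hz, remainder discarded) and flattened channel-major.
SWLDA regresses ±1 labels on the features with forward/backward selection:
add the candidate with the smallest partial-F p-value while p < 0.10, remove
any included feature whose p-value exceeds 0.15, stop at no change or 60
features (thresholds are the de-facto BCI-literature defaults; the study
names the method but not its thresholds). Coefficients are OLS on the final
set; with permissive thresholds the procedure reduces exactly to OLS, which
the tests exploit as an oracle. The implementation works on centered Gram
matrices with rank-one update formulas, so a 544-feature fit costs
milliseconds per step; candidates with near-zero partial variance are
skipped as collinear, and a visited-set guard breaks add/remove cycles.

AUC is the Mann–Whitney probability that a random target epoch outscores a
random non-target, ties counted ½. Cross-validation is stratified 10-fold
with a single seeded shuffle (stratification guarantees both classes per
fold at the 1:5 imbalance); feature selection is refit inside every training
fold; an empty-model fold contributes 0.5.

## Predictors and evaluation

Features are z-scored (sample SD) before combination because they carry
different units; within LOSO evaluation the z-parameters and the model —
including stepwise selection (p-enter 0.05 / p-remove 0.10, the referenced
statistical environment's defaults) — are refit on the 47 training subjects
for every held-out subject. Reported statistics: Pearson r between
predictions and outcomes with the t-transform p (n−2 df), F (= t² for
correlations, the regression ANOVA F for in-sample fits with its standard
df), R², and MSE with predictions and outcomes multiplied by 100 first
(squared errors on the native 0–1 AUC scale are too small to compare).
Outcomes stay on the native AUC scale for fitting. The predictor table
reports both in-sample and LOSO statistics for all seven predictors, with
and without the outlier screen (subjects below mean − 2.5 SD of the cohort
AUC; one-sided, matching the study's use of the rule to flag
under-performers only — a two-sided option exists).

Degenerate LOSO cases are reported as-is: an intercept-only model predicts
the training mean, whose leave-one-out variation is perfectly
anti-correlated with the held-out outcome (r → −1). This is a known
artifact of LOSO under the null, visible in the worked examples as strongly
negative LOSO r for uninformative features.

## Cohort statistics

Group contrasts use the top/bottom-10 performers (ties broken by subject id)
and a pooled-variance two-sample t-test (Welch optional). Channel-wise
correlation topographies attach Benjamini–Hochberg FDR flags at q = 0.1.
The task-length sweep recomputes all features from the first N = 5..40
trials and re-correlates with AUC (N ≥ 5 because the SD features need ≥ 5
trials).

## Problem sizes

Single-trial AUC is a per-epoch quantity: its level does not depend on how
many epochs are recorded, and cross-subject correlations only gain sampling
noise at smaller sizes. The package therefore runs its heavy scenarios
scaled down, as a design choice:

* test-suite cohort fixture: 20 cohorts × 48 subjects at 128 Hz, one test
  word, 4 repetitions, 5 folds (~4 minutes total);
* acceptance script: one 48-subject cohort at 256 Hz, two test words, 5
  repetitions, 10 folds (~1–3 minutes);
* the full-scale configuration (512 Hz, four words, 15 repetitions) is the
  `ParadigmConfig` default and runs the same code path.

## What the synthetic setting shows — and what it does not

Passing tests demonstrate that the estimators recover known ground truth
(injected latency jitter within 25%; amplitude monotonicity; chance-level
AUC under label shuffling; FDR calibration under the null) and that the
qualitative study-level structure emerges (latency variation negatively and
significantly predicts AUC in 20/20 simulated cohorts; correlations
stabilize by ~25 RSVP trials). They do not certify real-data behavior:
the generator has no ocular/EMG artifacts, no volume conduction, no
session-to-session drift, and a *single* latent quality factor. That last
simplification has a measurable consequence: the measured latency-variation
feature aggregates essentially all performance-relevant latent variation
(its peak-picking scatter grows with noise and shrinks with amplitude), so
the multi-feature models rarely beat it *out of sample* in simulation,
whereas the study's real cohort — where the features carry partially
independent information — found the stepwise combination strongest. The
acceptance suite asserts the real-cohort ordering and that assertion fails
honestly under this generator; see the test suite's cohort-properties
section.

## Known limitations

* Event onsets are rounded to the sample grid; at rates not divisible by
  the 10 Hz RSVP rate this leaves sub-sample timing jitter (≤ 0.5 sample).
* The 0.5 Hz high-pass has multi-second tails, so neighboring evoked
  responses leak marginally into each other's epochs (visible as a ~0.04 μV
  amplitude variation in the noiseless limit).
* Speller calibration runs (BRAIN/POWER) can be generated but play no role
  in the offline AUC definition, which cross-validates within the test
  runs.
* EDF export is not provided; sessions serialize to a simple directory
  format (JSON metadata + raw float32 + TSV events).
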