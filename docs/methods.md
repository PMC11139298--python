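# Methods

`voiceaudit` implements a bias-aware audit pipeline for machine-learning
screening of unilateral vocal fold paralysis (UVFP) from voice recordings.
Because clinical voice datasets of this kind are not publicly deposited, the
package pairs the analysis stack with a synthetic cohort generator whose
ground truth is known by construction; every stage is validated against that
ground truth or against independent numerical oracles.

## The synthetic cohort

`synth.generate_cohort` emulates a matched case-control voice study:

* **Participants.** `n_per_group` patients, each with one control matched on
  sex, smoking status, and age within three years. Sexes alternate so the
  two groups have identical sex counts.
* **Recordings.** Per participant: three sustained /a/ vowels and one reading
  passage split in thirds (the un-split passage is kept for clinician
  rating), 16 kHz mono, 16-bit PCM on export.
* **Source-filter synthesis.** A glottal impulse train with cycle-to-cycle
  period perturbation (jitter, % CoV) and amplitude perturbation (shimmer),
  smoothed by two one-pole low-pass stages (≈ −12 dB/oct glottal tilt),
  mixed with aspiration noise scaled after vocal-tract filtering so the
  harmonic-to-noise power ratio equals the requested HNR (dB), and passed
  through a cascade of second-order formant resonators. The sustained /a/
  uses textbook formants (700, 1220, 2600) Hz with bandwidths
  (130, 70, 160) Hz. The reading proxy concatenates voiced segments (~1 per
  second, several vowel targets, f0 declination of 0.25 st/s resetting every
  ~8 s like breath groups) separated by silent pauses (18% of time by
  default). The proxy's *local* statistics are duration-independent by
  design, so recording length itself is the only duration signal.
* **Pathology.** Additive shifts on per-participant baselines drawn from
  group-shared distributions. Defaults (mean magnitudes): jitter +0.8 pp,
  shimmer +1.8 pp, HNR −3 dB, f0 −2.5 st, intrinsic level −3 dB, pause
  fraction +0.05, formant bandwidths +110%. The last two reflect the
  clinical picture of glottal incompetence: air escape shortens phonation
  runs and damps the formant resonances. Each participant carries a common
  severity U(0.15, 1.45), but every dimension realizes its own severity
  (0.45 × common + N(0.1, 0.5), clipped positive) — a paralysis severe in
  breathiness need not be severe in pitch, which is what lets a redundancy
  analysis separate the channels. Per-recording session noise (±12% on
  perturbation values, ±1.5 dB HNR, ±2 dB level) keeps any single feature
  from becoming a clean separator. Magnitudes were calibrated so the cohort
  reproduces the separability regime the emulated study reports:
  multi-feature classifiers reach a median ROC AUC around 0.9 while single
  features stay at or below the mid-0.7s.
* **Recording biases** (each a switch):
  - *Duration bias*: control readings fixed at 3.5 s per third and control
    vowels at 4.11 s; patient reading thirds lognormal (median 8 s,
    σ = 0.55, cap 30 s) and vowels N(3.74, 1.3) s. 30% of patient passages
    received the same fixed cropping as controls — and mild cases more
    often than severe ones — which keeps a duration-only classifier strong
    (≈0.8) but not perfect, and makes the patients that any channel misses
    largely the same patients; both are properties of the audited dataset.
  - *Gain bias*: **compensatory** microphone gain — the operator boosts a
    weak voice toward a −25 dBFS target, plus a N(0.7, 1) dB offset,
    clipped to [0, 12] dB — and the noise floor (N(−55, 4) dBFS between
    sessions) rises by the gain, since amplification raises room noise too.
    Compensation is the crucial mechanism: it makes the *recorded* level
    stop tracking, and on average mildly invert, the true voice weakness,
    so patients come out louder and noisier than controls (the
    counterintuitive signature the audit is designed to catch) while
    recorded loudness ceases to be an honest pathology readout.
* **Clinician raters.** Three simulated raters score the un-split reading
  passage: each 0–100 scale is a clamped noisy reading of a latent driven by
  the true perturbation/breathiness parameters; the binary UVFP call
  thresholds the noisy severity latent; background-noise and
  recording-loudness categories threshold the true noise floor and
  post-channel RMS. Rater noise SD controls the downstream ICC through the
  variance-components identity ICC = s_b²/(s_b² + s_e²)
  (`noise_sd_for_icc`).
* **Seeding.** One master seed; every participant, recording, and rater
  stream is a `SeedSequence(entropy=seed, spawn_key=...)` child keyed by a
  fixed counter scheme, so identical specs reproduce byte-identical cohorts
  and partial regeneration is stable.

What the generator does *not* emulate: real connected speech (the reading
proxy has no phonetic or lexical content), perceptual realism, laterality of
the paralysis, device/channel frequency responses, or room acoustics beyond
a white noise floor. Passing tests therefore demonstrate that the analysis
machinery behaves correctly under the modelled statistical structure — not
that the screening problem is solved on real clinical audio.

## Acoustic features

`features.extract_egemaps` computes the 88 functionals of the extended
Geneva Minimalistic Acoustic Parameter Set (eGeMAPS v02) name set with an
in-repo extractor (32 ms Hamming frames, 10 ms hop):

* f0 by autocorrelation of the 900 Hz low-passed frame with window-taper
  correction, an octave-error guard preferring the shortest near-maximal
  lag, and parabolic refinement; voicing requires a corrected
  autocorrelation peak above 0.45 plus an energy floor.
* HNR from the spectral comb — power at harmonics of the frame f0 vs power
  midway between them, on a dedicated 64 ms window so the mainlobe stays
  narrower than half the harmonic spacing down to ~80 Hz. This estimator
  tracks aspiration noise nearly independently of pitch.
* Jitter/shimmer from glottal cycle marks picked on the fundamental band;
  relative period differences and dB amplitude differences of consecutive
  cycles.
* Formants F1–F3 by order-12 LPC (autocorrelation method, batched
  companion-matrix eigenvalues), with bandwidths from root radii and
  amplitudes relative to the f0 harmonic.
* Spectral balance (alpha ratio, Hammarberg index, 0–500 and 500–1500 Hz
  slopes, H1–H2, H1–A3, spectral flux) from the frame STFT; MFCC 1–4 from a
  26-band mel filterbank and orthonormal DCT.
* Loudness as a Stevens-law proxy (frame RMS^0.6); the equivalent sound
  level as 10·log10 of mean power (dBFS).
* Functionals: arithmetic mean and coefficient of variation for all
  descriptors; percentiles 20/50/80, their range, and rising/falling slope
  statistics for f0 and loudness; voiced/unvoiced segment statistics and
  loudness peak rate for prosody.

The contract for this module is the standard 88-name set, the count, and
physically correct responsiveness (each descriptor moves in the right
direction when its ground-truth synthesis parameter moves) — not bit-level
agreement with any specific reference extractor. Empty descriptor series
(e.g., no voiced frames in near-silence) yield 0.0 so vectors stay finite;
genuinely undefined cells become NaN and are imputed downstream with
medians learned on training splits only.

CPP uses 40 ms Hamming frames (10 ms hop), FFT zero-padded to the next
power of two ≥ 2× the window, the real cepstrum of the 20·log10 magnitude
spectrum, a peak search in quefrencies [1/330 s, 1/60 s], and a least-squares
regression line from 1 ms to the maximal analyzed quefrency; CPP is the peak
height above the line. All frames are analyzed (no voicing gate) — a
summary over all frames matches how the rest of the functionals are pooled;
the four summary statistics are mean, SD/mean (population SD), and the
20th/80th percentiles with linear interpolation.

## Redundancy removal

Distance correlation is implemented from the double-centering definition
(biased empirical estimator, the common package default); a constant vector
is defined to have dcor 0 so dead features are removable. The pairwise
matrix flattens each feature's centered distance matrix once and computes
all pairs as a single Gram product (float32 for wide/long tables).

The Independence Factor pass walks features in case-insensitive alphabetical
order: the first survivor is retained and every later survivor whose dcor
with it *exceeds* the threshold is removed and attributed to that keeper.
The threshold sweep [1.0 … 0.2] reuses one matrix; the parsimonious choice
is the smallest retained set whose best model scores within 0.03 of the best
full-feature model (ties toward the smaller threshold; if nothing qualifies
the full set is returned with a warning flag). Deduplication uses the full
pooled table by default (patients + controls), matching how the audit is
meant to be explained; per-group matrices are available for the heatmap
exports, and clustering is scipy average-linkage on Euclidean distances
between dcor-matrix rows.

A practical caveat surfaced by the tests: the empirical dcor of even
independent features is biased upward at small n (≈0.18 at 96 rows, and
rows cluster by participant, so the participant count is the effective n).
Absolute cutoffs such as 0.3 are therefore only meaningful at study-scale
cohorts; `remove_intensity_associated` raises if a cutoff removes every
feature.

## Model evaluation

Four fixed scikit-learn configurations: L1 logistic regression (liblinear),
SGD logistic regression with elastic-net (max_iter 5000, early stopping),
random forest (defaults), and an MLP (one hidden layer of 100 ReLU units,
max_iter 1000, alpha 1). All run inside a StandardScaler pipeline — the
features carry heterogeneous physical units (Hz, dB, seconds) and the
linear/neural models would otherwise be dominated by the large-valued
columns.

Splits are participant-level bootstrapped group-shuffle: each of 50
iterations holds out 20% of the participants with equal per-group counts
(all samples of a participant stay on one side), the rest train. Scores are
class-1 probabilities (or decision values), summarized as the median ROC AUC
with an empirical 5th–95th percentile interval. The permutation null refits
each model with training labels permuted at participant level (test labels
untouched); the empirical p-value uses the add-one formula
p = (1 + #{null ≥ observed median}) / (1 + n_splits), which never returns 0
— note it cannot fall below α = 0.05 with fewer than 20 splits.
Benjamini–Hochberg (statsmodels) controls the FDR across models. Per-split
RNG streams derive from (seed, split index, model name) so model comparisons
share splits.

## Explainability

Kernel SHAP is implemented natively: coalitions are drawn *from* the Shapley
kernel distribution (sizes ∝ (M−1)/(s(M−s))), absent features are filled
from a ≤25-point k-means summary of the training background, and the
weighted regression is solved with the efficiency constraint
Σφ = f(x) − E[f] eliminated algebraically — so local accuracy
(base value + Σφ = f(x)) holds exactly for every explanation. When the
feature count allows full enumeration the exact kernel weights are used; in
the under-determined sampled regime an L1 (lasso) pre-selection picks the
support before the constrained solve. Per model, importance is the mean
|SHAP| over explained test predictions (a fixed-size subsample per split),
averaged over splits and weighted by the model's median AUC; the
cross-model rank is the weighted mean of the per-model rankings with the
same weights. Weighting before ranking vs after is ambiguous in the field's
descriptions; this package ranks the weighted importances and then averages
ranks with performance weights, which reduces to the plain mean rank when
all models perform equally.

## Bias audit and mitigation

* Duration probe: the standard evaluation run on a one-feature table
  (audio duration).
* Intensity direction: per intensity-category feature, group means and a
  flag when the patient mean exceeds the control mean — the
  counterintuitive direction for a weak-voice disorder, hence a bias
  signature.
* Reliability: ICC(2,1) (two-way random effects, absolute agreement, single
  rater) from ANOVA mean squares, with a consistency-type ICC(3,1) switch;
  Light's kappa as the mean pairwise Cohen's kappa (degenerate pairs — a
  constant rater — count 0). Agreement labels: poor < .40 ≤ fair < .60 ≤
  good < .75 ≤ excellent.
* Clinician accuracy: a binary call admits one operating point, so its AUC
  is (sensitivity + specificity)/2; the median across raters is reported.
* Rating-based models: the six 0–100 perceptual scales averaged across
  raters (clinician6) and the two ordinal recording-condition ratings
  encoded 0/1/2 and averaged (clinician2) run through the standard
  evaluation.
* Mitigation: reading recordings trimmed to the fixed control duration
  (shorter ones excluded with a warning; vowels cannot be duration-matched
  and are left alone), features re-extracted from the trimmed audio, then
  all intensity-category features plus any feature whose dcor with one of
  them reaches the cutoff (0.3 or 0.4, computed on the trimmed pooled
  reading table) are dropped, and the evaluation is repeated. The report
  carries pre/post score distributions, the removal manifest with
  attributions, and retained feature counts.

## Problem sizes and numerical choices

The test suite runs everything at the smallest scale that preserves the
statistical structure: null calibration at 40 participants per group with
the full 50 splits; the explainability recovery at 20 per group (vowel
task, 10 splits, 8 explained rows per split). The two mitigation
experiments run at full study scale (77 per group, reading task, 20
splits) because the absolute dcor cutoffs (0.3/0.4) are only calibrated
for ~150 effective samples — at toy scale the dcor noise floor alone
crosses the cutoff. The acceptance script reproduces the null-calibration
quantity at full scale (77+77, 50 splits, all four models).

Other numerical choices: percentiles by linear interpolation; population
(ddof = 0) standard deviations in coefficient-of-variation functionals;
`stddevNorm` defined as 0 when the mean is 0; ROC AUC requires both classes
in the test split (the split plan guarantees it); WAV export clips to
[−1, 1] and quantizes to int16.

## Known limitations

* The 88 functionals are name- and semantics-compatible with the standard
  set but numerically the package's own; models trained on them do not
  transfer to tables produced by other extractors.
* The reading proxy is statistically, not phonetically, speech-like; rater
  simulation is a low-dimensional latent model.
* Kernel SHAP with sampled coalitions is an approximation whose variance
  grows with feature count; only the additivity identity is exact.
* The biased dcor estimator's small-sample inflation makes absolute
  association cutoffs sample-size dependent (see above); a
  permutation-calibrated cutoff would remove this dependence but is not
  what the audited procedure specifies.
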