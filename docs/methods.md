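# Methods

`prosodia` implements a fully automated acoustic dysprosody-assessment
pipeline: a raw speech recording is segmented into utterance-like spans,
each span's intonation is stylized into a small set of tonal targets, a
battery of 205 prosodic predictors is measured per utterance, and ordinal
severity classifiers ("no deviation" < "mild" < "moderate to severe") are
tuned, averaged, stacked and evaluated with macro one-vs-rest metrics.
This note records the models, the parameter choices and their rationale,
what the synthetic corpus does and does not emulate, and known limits.

## Utterance detection

The built-in detector is an energy gate: frame RMS in dB (25 ms window,
10 ms hop); threshold `max(noise_floor + margin_db, floor_db)` with the
noise floor at the 10th percentile of frame levels, `margin_db = 12`,
`floor_db = −55` (re digital full scale). Supra-threshold frames are merged
across gaps < 0.3 s, spans shorter than 0.25 s are dropped, and 0.05 s of
padding is added at both ends. All five numbers are config keys. The
detector is deliberately model-free so the package runs offline; a
pretrained neural (e.g. overlap-aware) segmenter can be plugged in through
`vad.register_external_vad`, whose spans are validated (ordered,
non-overlapping) and then used verbatim.

## Two-pass f0 tracking

f0 is estimated by normalized autocorrelation (40 ms window, 10 ms hop —
the 10 ms step is fixed throughout), with parabolic peak interpolation and
a voicing decision at normalized-peak ≥ 0.45 (config key). A first pass
searches the very wide 60–750 Hz space; the first quartile q1 of its voiced
values (median-smoothed, width 5, before the quartile only; linear
interpolation quantile) narrows the final pass to
`[0.75·q1, q1·2^1.5]` — three quarters of q1 up to 1.5 octaves above it.
The narrowed space removes octave errors without per-speaker (age/sex)
range tuning; a property test asserts the two-pass track is never less
accurate than the single pass on planted glides.

## Momel stylization and INTSINT coding

The voiced track is reduced to Momel target points (MTPs). Every voiced
frame contributes a candidate from a local quadratic regression over a
sliding 300 ms window (frames deviating > 5 % from the first fit are
dropped and the fit repeated once): the parabola apex when it falls inside
the window — apices pile up at intonational turning points — otherwise the
fitted value at the frame. Candidates are averaged within 200 ms reduction
windows; the first and last voiced frames (at their locally fitted f0)
always anchor the contour. Window sizes follow the canonical published
implementation of the algorithm and are config keys. The macro-prosodic
contour through the MTPs is the unique C1 quadratic spline with knots at
the midpoints between consecutive MTP times (the two outermost midpoints
are dropped, which is what makes the interpolant unique); a test checks it
against an independently solved piecewise system to 1e−9.

INTSINT assigns each MTP one of eight levels. With key K (Hz) and span S
(octaves): T = K·2^(S/2), M = K, B = K·2^(−S/2); S(ame) repeats the
previous modelled f0; H/L sit at the log-frequency midpoint between the
previous target and the T/B level; U/D a quarter of that log distance.
K and S are found by grid search — K in 50 steps across ±0.5 octave around
the geometric-mean MTP f0, visited outward from the mean so exact ties
resolve to the canonical mean-key coding; S from 0.5 to 2.5 octaves in
0.05 steps. Within each (K, S) labels are assigned greedily left to right
(first label restricted to the absolute levels T/M/B), minimizing
|Δ log f0|; the returned annotation minimizes the summed squared log error
over the grid. All errors are log-frequency (octave-scaled) because every
level of the coding model is defined on a log scale. A dynamic-programming
label assignment would be exact for pathological contours; the greedy pass
is the canonical choice and a brute-force test confirms it attains the
global optimum on generated contours.

## Acoustic measurements at MTPs

Each MTP is measured in a 30 ms Hann window centered on its time (config
key; the window length is a design decision — only "a window surrounding
the target" is prescribed by the battery). dB values are referenced to
digital full scale; no SPL calibration is attempted.

* **Intensity**: 10·log10(mean square), silence floored at −120 dB.
* **SER**: 10·log10 of band power 0–1 kHz over 1–5 kHz; a vanishing high
  band caps at +60 dB (flagged).
* **L2−L1, L3−L1**: harmonic levels read at the spectral peak nearest
  k·f0 (±f0/4, parabolic interpolation); L3 is undefined above Nyquist.
  The "corrected" variants subtract each nearby formant's resonance gain
  (discrete two-pole magnitude normalized to unit DC gain) using formants
  from LPC root-solving (pre-emphasis 0.97, order 2 + rate/1000,
  near-duplicate roots merged) and bandwidths from the Hawks–Miller
  f0-scaled polynomial regression. Both formulas are verified against
  independent in-test transcriptions.
* **C1**: first Mel-frequency cepstral coefficient — 26 area-normalized
  triangular filters 0–Nyquist on the power spectrum, log energies floored
  60 dB below the strongest filter (keeps C1 finite when a narrow low
  filter falls between harmonics), orthonormal DCT-II, index 0 (gain)
  discarded, so C1 is exactly gain-invariant.
* **SLF / SLF6D**: least-squares polynomial fits (order 1 slope; order 6,
  six non-constant coefficients) to the 0–5 kHz log-magnitude spectrum,
  frequency in kHz to keep coefficients well-scaled.

## The 205-predictor battery

Quantities at MTPs and their successive differences are summarized per
utterance by six statistics (min, max, mean, SD, CV = SD/mean, IQR with
linear-interpolation quantiles; SD uses n−1). Domains and subtotals: time
15, f0 16, intensity 16, spectral tilt 158 — 205 total, with a frozen name
order asserted by checksum. Two slots in the published layout are
degenerate duplicates and are reconstructed here: the second
duration slot is implemented as the MTP time span (last − first MTP time),
and the repeated "f0 key" row in the intensity domain as the utterance
mean intensity. The 7th SER slot is the long-term-average-spectrum (LTAS)
SER; the 7th ΔSER slot is the RMS deviation of per-MTP SER about the LTAS
value. Utterance-level intensity statistics cover the stylized region
(first to last MTP) so onset/offset ramps at the detected span edges do not
set the minimum. Utterances with fewer than 2 MTPs are excluded with a
reason code rather than imputed.

## Classification protocol

* **Split**: recording-level stratified 75/25 (all utterances of a
  recording on one side; per-class proportions preserved up to rounding).
* **Screening**: predictors linked by |Spearman ρ| > 0.9 form connected
  components; each component keeps only the member with the highest
  |Spearman ρ| against the ordinal outcome. Constant predictors correlate
  as 0.
* **Candidates**: maximin Latin hypercube over the fixed ranges (SVM cost
  9.96e−4–31.6 log-scaled; elastic-net total penalty 0–0.998 linear, L1
  share 6.7e−4–0.999 log-scaled; forest trees 1–2000, predictors per split
  1–74, minimum node size 2–40; neighbors 1–15 with nine distance kernels
  and Minkowski exponent 1–2 — the exponent range is a design decision, no
  range being prescribed). The published max-entropy/variogram design is a
  space-filling family; maximin LHS is the standard reproducible stand-in.
  Default 1000 candidates; tests use 20.
* **Tuning**: 10-fold cross-validation on mean log loss, folds stratified
  by label *and grouped by recording* when recording ids are available:
  labels are per-recording, so utterance-level folds let hyperparameter
  selection exploit speaker identity and favor parameters that do not
  generalize to unseen speakers (observed directly on the synthetic
  corpus: grouped folds select shallower forests and raise held-out-speaker
  balanced accuracy from 0.78 to 0.81).
* **Models**: polynomial-kernel SVM (calibrated probabilities), random
  forest, kernel-weighted k nearest neighbors (kknn-style distance
  kernels), and a proportional-odds ordinal regression with an elastic-net
  penalty fitted by L-BFGS on the smoothed-L1 penalized likelihood (no
  installed package provides a penalized ordinal model, so this learner is
  implemented here). All inputs pass through median imputation (and
  standardization where the learner needs it).
* **Averaging**: the ten fold fits of the winning candidate are combined by
  arithmetic probability averaging — parameter averaging is undefined
  across forests and kNN, so probability space is the only model-agnostic
  choice.
* **Stacking**: non-negative weights on the averaged base models, summing
  to one, minimizing the log loss of the convex combination of their
  out-of-fold probabilities — i.e. each model is weighted by its
  demonstrated strength on data its fold fits did not see.
* **FIRM importance**: for each predictor, its values are split into 10
  quantile bins; the model's mean predicted class probabilities are
  computed with the predictor clamped to each bin median; the importance is
  the standard deviation of that conditional expectation across bins (the
  root mean squared change of the model output), averaged over the three
  classes. Exact FIRM needs the true feature distribution; the quantile-bin
  estimate is the standard partial-dependence-style approximation. Bin
  count is a config key.
* **Baseline**: an unpenalized ordinal regression on the single
  utterance-wide f0-SD predictor — the field's traditional dysprosody
  proxy — serves as the comparison model.

## Evaluation

Confusion matrices use truth rows and prediction columns with classes
ordered none < mild < moderate-severe. The report is the unweighted
(macro) mean of one-vs-rest sensitivity, specificity, PPV, NPV, balanced
accuracy and F-score; when some class is never predicted the macro PPV is
reported undefined (a dash) and that class's F contributes 0. Per-class
values are computed in exact rational arithmetic from the integer counts,
and display rounding is half-up at 2 decimals on the exact value, so
printed-table comparisons cannot be disturbed by binary floating-point
boundary cases. Cohen's kappa uses marginal-product chance agreement
(defined as 1.0 when both raters are constant and identical); consensus
ratings take the mode with ties broken toward the more severe category (a
design decision — no tie rule is prescribed); one-vs-rest ROC uses a
threshold sweep with trapezoidal area.

## Synthetic speech and corpus

Clinical recordings are sensitive personal data and cannot be shipped, so
all end-to-end validation uses synthesized speech: an additive harmonic
source follows the quadratic interpolation of planted (time, f0) targets;
per-target spectral tilt (dB/octave), linearly interpolated between
targets, shapes the harmonic amplitudes; a resonator cascade at
500/1500/2500 Hz adds vowel-like formants; an aspiration-noise floor at
−45 dB keeps energy between harmonics as in real phonation; a
piecewise-linear dB envelope controls intensity (the source is normalized
before the envelope, so the envelope sets realized levels exactly); pauses
are inserted as silence. Single utterances default to 48 kHz; the corpus
synthesizes at 16 kHz, which is sufficient because every measured band lies
below 5 kHz.

The labelled corpus plants the effect structure that severity tracks in
dysprosodic speech: per speaker (labels are speaker-level, mirroring
per-recording clinical ratings), a key is drawn uniformly in 100–220 Hz;
per utterance, 4–9 targets with 0.25–0.45 s gaps; f0 steps are drawn
Normal(0, 0.22 oct · m^severity) on a log2 scale with reflecting bounds at
±0.7 octave (reflection flips step signs only, so the planted step-SD
contrast between classes is exact); per-target tilt is Normal(−8, 4 ·
m^severity) dB/oct clipped to [−16, −2] (the range over which the tilt
measures respond above the noise floor); per-target intensity offsets are
uniform over ±9 · m^severity dB. The default multiplier m = 0.5 per
severity step is a moderate, realistic contrast; `synth.strong_effects()`
sets m = 0.3 — severity 2 retains 9 % of the healthy f0-step SD
(~0.3 semitones per step), i.e. clinically overt monopitch and
monoloudness — and is the condition under which end-to-end recovery is
demanded of the pipeline.

What the corpus does **not** emulate: consonants and segmental structure,
jitter/shimmer/voice-quality deviation, articulation-rate effects, speaker
sex/age covariates, channel/recording differences, and rater disagreement
(labels are noiseless). Passing the end-to-end test therefore shows that
the pipeline recovers planted prosodic structure through the entire
signal-processing and learning chain — it does not certify clinical
accuracy on real dysarthric speech.

## Problem sizes and determinism

The validation corpus is 20 speakers × 5 utterances (~100 utterances,
≈260 s of audio); end-to-end training tunes the forest over 20
space-filling candidates in 10 grouped folds. Every random draw flows from
an explicit integer seed through `numpy.random.default_rng` (per-speaker
child seeds derive from the corpus seed), so corpora, splits, folds,
candidate sets and fits reproduce bit-identically across runs.

## Known limitations

* The energy VAD occasionally splits one read sentence at a deep intensity
  dip; downstream statistics then describe the pieces. Utterance counts are
  therefore approximate, as expected of unsupervised segmentation.
* The LPC formant tracker assumes vowel-like frames; on noise it returns an
  empty list and the harmonic-level correction degrades to the identity.
* The f0-step / tilt / intensity channels of the synthetic corpus are
  measured through shared machinery (harmonic alignment with formants
  couples f0 to SER and intensity), so the three planted effects are not
  perfectly orthogonal in feature space.
* Severity classes in the corpus differ only in variability parameters;
  real dysprosody likely also shifts level quantities (mean f0, mean
  intensity) that are deliberately left class-neutral here.
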