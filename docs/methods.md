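# Methods

`microfusion` implements a multimodal emotion-recognition pipeline that
uses facial micro-expressions to locate the most emotional moment of a
trial and then analyses only a region of interest (ROI) around that
moment in every modality.  This note documents the model, the synthetic
data it is validated on, the numerical choices, and the limitations.

## Problem setting

A *trial* is one participant watching one emotion-eliciting video clip
while keeping a poker face, with four synchronized recordings: facial
video (30 fps), multi-channel EEG (128 Hz), and single-channel GSR and
PPG (128 Hz).  After each clip the participant reports arousal and
valence on the 1–9 SAM scale.  The task is binary classification of
arousal and of valence, with ratings binarized at five (rating > 5 →
"high"; the tie at exactly 5 goes to "low").  Evaluation is
subject-independent: leave-some-subject-out cross-validation over six
folds, reporting the unweighted fold mean of accuracy, precision, recall
and F1 with "high" as the positive class.

## Pipeline

1. **Apex spotting.**  Under poker-face instructions the first and last
   frames of a trial show the face at rest, so they stand in for the
   onset and offset frames of whatever micro-expression occurs.  Ten
   regions are laid over the face crop (eyebrows, eyes, nose root, nose
   wings, mouth corners, chin — the components where facial muscle
   movements concentrate).  Each frame *f* is scored by
   `mean over region pixels of (|f − first| + |f − last|) / 2`,
   and the apex is the curve's argmax (earliest frame on ties).  Whether
   the two reference differences should be summed or averaged is not
   observable from the argmax (they differ by a factor of two), so the
   average is used.
2. **Video ROI.**  A fixed window of 20 or 60 frames is centred on the
   apex (`window // 2` frames before it); windows overrunning the trial
   boundary are shifted, never shrunk, so the classifier input shape is
   constant.  Each ROI frame is cropped to the detected face box,
   converted to grayscale, min–max normalized to [0, 1] per frame and
   resized to 64 × 64 (bilinear), giving a `window × 64 × 64` tensor.
3. **Signal ROI.**  The apex frame index maps into each signal stream as
   `round(apex / fps × rate)`.  EEG is band-passed 1–45 Hz (brain-wave
   range) with a common average reference; GSR is band-passed 0.1–15 Hz
   and median-filtered (0.5 s kernel, reflected edges) against transient
   artifacts; PPG is band-passed 0.7–2.5 Hz (pulse band).  All filters
   are 4th-order Butterworth applied forward–backward (zero phase — the
   filter family and order are not prescribed anywhere, so the standard
   biosignal choice is used), and every stream is z-scored per channel
   over the whole trial.  A window of 15 s (or the whole trial, "all")
   centred on the apex sample is then cut, boundary-shifted like the
   video ROI.
4. **Features.**  The signal ROI is split into non-overlapping 1 s
   windows (a trailing partial window is dropped).  Per window: EEG
   yields the five band powers — delta 1–4, theta 4–8, alpha 8–12, beta
   12–30, gamma 30–45 Hz — from a plain (boxcar) periodogram, power
   averaged over in-band bins with the `[low, high)` convention and then
   over channels, so the stored sequence is `n_windows × 5` regardless
   of montage size; GSR yields [mean, SD, mean |Δ|, mean |Δ²|]; PPG
   yields [mean, SD].  SDs are population SDs throughout.  GSR and PPG
   features concatenate (GSR first) into a six-feature "physiological"
   vector.
5. **Classifiers.**  Three per-target models: a small 3D CNN on the
   video tensor, and either a two-layer stacked LSTM (80 then 30 units)
   on the EEG and physiological sequences or a classical model (RBF-SVM
   with C = 200, 5-NN, or 500-tree random forest) on the per-trial mean
   of the window features.  All training is cost-sensitive with balanced
   class weights `w_c = N / (2 N_c)`.  KNN has no native cost-sensitive
   fit, so its neighbour-vote fractions are re-weighted by the class
   weights and renormalized.
6. **Fusion.**  Decision-level: either a majority vote of the three
   binary decisions, or the weighted probability sum
   `p^x = a·p_video^x + b·p_EEG^x + c·p_physio^x` with `a + b + c = 1`.
   The weights are found by exhaustive search on the 0.01 simplex grid
   (5,151 triples) maximizing F1 on the *training* trials of the fold;
   ties resolve to the lexicographically smallest (a, b).  A fused
   probability of exactly 0.5 resolves to "high".

## The trainable networks

No deep-learning framework is part of the dependency set; both networks
are compact numpy implementations (`microfusion._net`) trained with Adam
on a class-weighted softmax cross-entropy, fully seeded, and verified by
central-difference gradient checks in the test suite.

**3D CNN** (video): spatial average-pool (1, 2, 2) → two blocks of
3×3×3 convolution (8 then 16 filters, leaky ReLU, 2×2×2 max-pool) →
dense 64 → dropout 0.5 → softmax 2.  Two departures from a textbook
stack proved necessary:

* *Input standardization.*  The neutral face is a large constant
  component shared by every trial while the class signal is a tiny
  transient; feeding raw [0, 1] tensors makes the quickest loss
  reduction "predict the prior", after which units die and training
  stalls at ln 2.  Inputs are therefore centred on the training-set mean
  tensor and scaled by the global residual SD (training-set statistics
  stored with the model), after which the planted movements are O(5σ)
  events and training converges in a few epochs.
* *Initial spatial average-pool.*  Halving 64 × 64 to 32 × 32 before the
  first convolution cuts the arithmetic 4× with no measurable loss on
  region-scale intensity patterns, which keeps a six-fold experiment in
  CPU minutes.  Disable with `spatial_prepool=1`.

Defaults: Adam lr 1e-3, batch 8, 50 epochs (the reference experiment
below uses 5 — see "Problem sizes").

**Stacked LSTM** (EEG/physiological sequences): features are z-scored
per dimension with training-set statistics, then two LSTM layers (80,
30 units; forget-gate bias 1) feed a 2-unit softmax head from the final
hidden state.  Adam starts at lr 1e-3 and halves on a validation-loss
plateau (patience 5, min-delta 1e-4) down to a floor of 1e-4; the
validation split is the last 20 % of training subjects.  Batch sizes per
modality: EEG 128, GSR 32, PPG 64; the fused GSR+PPG "physio" sequence
uses 32.  100 epochs by default.

## Synthetic data

Real datasets of this kind are access-restricted, so validation uses a
generator (`microfusion.synth`) with known ground truth.  Each trial
draws a latent (arousal, valence) pair — cycled deterministically over
trials so the dataset is balanced up to rounding — an apex frame
(uniform over the central 70 % of the trial) and a micro-expression
duration (uniform over 65–500 ms, the accepted duration range).

* **Frames**: a deterministic neutral-face intensity field (ellipse head
  with darker landmark patches — *not* a photorealistic face; spotting
  operates on regional pixel differences, which this exercises fully)
  plus i.i.d. Gaussian pixel noise (SD 0.02), with one additive bump of
  amplitude 0.10 (5× the noise SD) in a single facial region, triangular
  in time and peaking exactly at the apex.  The region encodes the
  class: eyebrows for high arousal, mouth corners for low; left side for
  high valence, right for low.
* **EEG**: per-channel pink (1/f) noise; inside apex ± 7.5 s (half the
  default signal ROI), a Hann-tapered oscillation whose band depends on
  the state — beta + gamma for high arousal, theta for low, plus an
  alpha component that is strong and left-lateralized for high valence
  and weak otherwise.  `band_shift_strength` (default 1, in units of the
  baseline SD) scales it.
* **GSR**: tonic level + slow drift + phasic skin-conductance responses
  (exponential rise 0.7 s / decay 2.5 s); ~2 spontaneous responses per
  minute plus a cluster near the apex whose expected count is 3 for high
  arousal vs 0.5 for low, scaled by `physio_effect_strength`.
* **PPG**: a two-harmonic pulse at 1.1 Hz (low arousal) to 1.4 Hz
  (high), with a Gaussian amplitude swell near the apex for high
  valence.
* **Ratings**: drawn to agree with the latent state (rating in 6–9 for
  "high", 1–5 for "low") with probability `rating_fidelity` = 0.95,
  independently per dimension — so even a perfect decoder tops out
  around F1 ≈ 0.95 against the rating-derived labels.

Determinism: one seed feeds a `SeedSequence` that spawns one child per
trial, so datasets are bit-identical across runs and independent of
generation order.  What the generator does *not* emulate — blinks, head
pose, lighting drift, electrode artifacts, rating drift within subjects,
inter-subject physiological variability — bounds what passing tests
mean: they demonstrate that the pipeline recovers the signal it is
designed for, not that it reaches any particular accuracy on real
recordings.

## Problem sizes and runtimes

The reference experiment (`standard_synthetic_experiment`) uses 23
subjects × 10 trials of 20 s, the 20-frame video ROI and the 15 s signal
ROI, with 12 CNN epochs and 40 LSTM epochs — the synthetic effects are
strongly separable and converge well before the full-scale defaults,
and the CNN count is set high enough that the network converges
decisively instead of lingering near its near-uniform initial outputs
(where binary decisions would be threshold artifacts).  A complete
six-fold run takes ≈ 6 minutes on one CPU core; the null condition (all
effect strengths zero, 18 subjects) adds ≈ 5 minutes.  Generator
defaults mirror the emulated acquisition (80 s trials, 30 Hz video,
128 Hz signals) but the reference experiment shortens trials to 20 s,
which leaves the apex-centred ROIs and all contracts intact.

A caveat on null-condition F-scores: a high-capacity model that
memorizes pure noise can still carry a whole-fold decision bias, and
because F1 is a concave function of the predicted-positive rate, the
fold-mean F1 of the video CNN on null data scatters noticeably around
chance across seeds (≈ 0.33–0.49 observed) even though its accuracy sits
at 0.5.  The sequence models, whose null predictions vary per trial,
concentrate much more tightly around F1 = 0.5.

## Numerical choices and edge cases

* Constant channels z-score to zeros (with a warning) rather than NaN.
* A constant image frame min–max-normalizes to its clipped value (an
  all-white frame stays 1).
* Degenerate precision/recall (empty denominator) is reported as 0,
  and F1 as 0 when precision + recall = 0.
* A face lost mid-ROI reuses the last valid box (keeps tensor shape); a
  trial whose *first* frame has no detectable face is excluded and
  counted.
* `sosfiltfilt` (second-order sections) keeps the 0.1 Hz GSR high-pass
  numerically stable at 128 Hz.
* Random-forest, SVM (Platt calibration) and both numpy networks are
  seeded; repeated runs with one seed reproduce reports exactly.

## Known limitations

* The face detector used on synthetic data is an oracle (the generator's
  known box); a luminance-threshold detector is bundled and any callable
  `frame -> box | None` can be plugged in, but no pretrained neural
  detector ships with the package.
* Single apex per trial; overlapping or repeated micro-expressions, and
  macro-expression contamination, are out of scope.
* The DEAP-style 8 s lead trim (`trim_lead`) is provided but unused by
  the synthetic pipeline, whose trials have no baseline segment.
* Classical classifiers see only the mean of the window features; richer
  aggregations (quantiles, slopes) were deliberately not added.
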