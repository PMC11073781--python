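# Methods

## Problem setting

Abdominal fetal ECG extraction works on a multichannel recording from
electrodes on the maternal abdomen. Each lead is a superposition of the
maternal ECG (large, ~60–100 bpm), the fetal ECG (typically 3–10× smaller,
~110–160 bpm) and noise. The package detects the *fetal* R-peaks directly
from the 12-lead composite, without first reconstructing a clean fetal
waveform: the record is cut into contiguous 65-ms frames and a recurrent
classifier decides, frame by frame, whether a fetal R-peak lies inside.
65 ms sits between published fetal QRS duration estimates (~50–70 ms at
1 kHz), so one frame spans roughly one fetal QRS complex.

## Synthetic data model

Real abdominal datasets with fetal R-peak ground truth are scarce and
usually confidential, so the package ships a generative model
(`sigsim`) used for training and for all quantitative tests.

* **Beat morphology.** Each beat is a sum of five Gaussian bumps (P, Q, R,
  S, T) on a phase axis θ ∈ [−π, π), the R wave at θ = 0 — the standard
  Gaussian-sum ECG template. Amplitudes are relative to R = 1; the R wave
  must strictly dominate. Separate default templates are used for the
  maternal and fetal sources (the fetal QRS is narrower in phase).
* **Rhythm.** R-R intervals are i.i.d. truncated-normal draws (±3 SD, floor
  0.2 s), i.e. a renewal process parameterized by heart-rate mean and SD.
  No autonomic variability spectrum is modelled. Defaults: maternal
  80 ± 3 bpm, fetal 140 ± 5 bpm; cohort generation draws per-subject means
  from 60–100 and 110–160 bpm.
* **Lead mixing.** Source traces are normalized to unit RMS, then each of
  the 12 leads receives `g_m·maternal + g_f·fetal` with `g_m ~ U(0.5, 1.5)`
  and `g_f = ±ratio·g_m·U(0.9, 1.1)` — the sign random per lead, mimicking
  bipolar electrode polarity. The fetal-to-maternal amplitude ratio
  (default 0.3) therefore holds per channel to within ±10%. Mixing is
  strictly linear in the sources for a fixed seed.
* **Noise.** Per lead: a baseline-wander sinusoid at a random frequency in
  0.05–0.45 Hz, a powerline tone at 50 or 60 Hz, and white Gaussian noise.
  Levels are absolute RMS in signal units (defaults 0.1 / 0.05 / 0.1
  against a unit-RMS maternal source scaled by its lead gain).
* **Quantization.** 16-bit uniform quantization over ±10 signal units.
  Unit-RMS sources with gains up to 1.5 produce QRS peaks near 7 units, so
  ±10 leaves ADC headroom; clipping would otherwise break the linearity of
  the mixture.

What the simulator does **not** model: uterine EMG, electrode motion
artifacts, fetal position changes, morphology drift, arrhythmias, twins,
and any coupling between maternal and fetal rhythms (overlapping QRS
complexes occur freely and are the hard cases). Passing synthetic tests
therefore demonstrates the pipeline's mechanics and its behaviour under the
stated noise model, not clinical performance.

## Preprocessing

Filtering is zero-phase: a second-order 0.05 Hz Butterworth highpass
(forward–backward with Gustafsson initial conditions — the 0.05 Hz corner
lies four decades below Nyquist, where a combined bandpass design is
ill-conditioned and ordinary edge padding leaks a slow transient), a
fourth-order 100 Hz lowpass, then an IIR notch (Q = 30) at the powerline
frequency. Standardization is per channel — 12 means and SDs estimated
from the training records only and frozen for test data. Frames are
non-overlapping, contiguous, `round(fs·0.065)` samples long; a trailing
remainder shorter than one frame is dropped. Labels use the half-open
convention: frame *i* is Class 1 iff a peak *p* satisfies
`start_i ≤ p < start_i + frame_len`, so a boundary peak is labeled exactly
once.

Class weights follow `w_c = n_s / (n_c · n_s_c)` with `n_c = 2`: balanced
labels give (1, 1); at a positive fraction of 0.1577 the weights are
(0.59, 3.17).

## Detector

A sequence-to-label classifier: three stacked bidirectional LSTM layers,
dropout between them, a fully connected layer applied to the final
recurrent state (forward direction's last step concatenated with the
backward direction's first-aligned step), and a softmax over two classes.
With hidden sizes (H₁, H₂, H₃) = (200, 100, 50) per direction the weight
matrices are (8H₁ × 12), (8H₁ × H₁), (8H₂ × 2H₁), (8H₂ × H₂), (8H₃ × 2H₂),
(8H₃ × H₃) and (2 × 2H₃) — i.e. 1600×12, 1600×200, 800×400, 800×100,
400×200, 400×50 and 2×100. A narrower variant (100, 50, 20) is selectable
through `DetectorConfig`.

Everything is implemented on numpy arrays: the forward pass, full
backpropagation through time (verified against finite differences), inverted
dropout, Adam (β₁ = 0.9, β₂ = 0.999), global-L2-norm gradient clipping at
1.0, and a step learning-rate schedule that drops once by 10× at
⌈epochs/2⌉. Weights are float32, Glorot-uniform initialized, forget-gate
bias 1. Training minimizes the class-weighted cross-entropy
`mean(w_yᵢ · −log p_yᵢ)`; with unit weights this equals the ordinary
cross-entropy. All randomness (init, shuffling, dropout, augmentation)
flows from one seed, so identical seeds reproduce identical training runs.

**Montage invariance.** Bipolar abdominal leads have arbitrary polarity
and subject-specific gains; each subject's fetal projection flips sign
lead by lead. A classifier trained on a handful of subjects would
otherwise memorize the training montages and fail on an unseen subject.
Two mechanisms address this: during training, each mini-batch sample is
multiplied per channel by a random sign and a gain drawn from
U(1−j, 1+j) (default j = 0.5); at prediction time the Class-1 posterior
is averaged over eight deterministic sign patterns (identity plus seven
seeded random flips). Setting `polarity_votes=1` disables the latter.

## FECGPP (detection post-processing)

The classifier output is refined into a physiologically plausible event
sequence in three steps:

1. **Run merging.** Each maximal run of consecutive Class-1 frames becomes
   one candidate event at the center sample of the run's
   maximum-posterior frame, with that posterior as its confidence.
2. **Refractory pass.** While two events lie closer than `rr_min_ms`
   (default 250 ms — a 240-bpm fetal ceiling), the lower-confidence member
   of the closest offending pair is deleted.
3. **Short-interval suppression.** The absolute floor cannot catch split
   beats in slow rhythms (a false positive 260 ms after a true beat
   survives a 250-ms floor even when the subject's R-R is 500 ms), so a
   rhythm-adaptive pass removes the lower-confidence member of any pair
   whose interval is below `short_factor` (default 0.55) times the running
   median R-R. This pass uses a wide centered 21-interval median so that
   clusters of false positives cannot drag their own reference rhythm
   down far enough to pass their own test.
4. **Gap fill.** Where an inter-event interval exceeds `gap_factor`
   (default 1.8) times the running median of nine centered intervals
   (centered, again, for robustness at the record edges),
   the highest-posterior unused frame inside the gap whose posterior is at
   least `promote_floor` (default 0.2) and which keeps the refractory floor
   and the short-interval rule
   to both neighbours is promoted to an event. The pass repeats until no
   insertion occurs, so gaps spanning several missed beats are recovered
   and the whole operator is idempotent — re-running FECGPP on its own
   output changes nothing.

`gap_factor = 1.8` flags a single missed beat without firing on normal
heart-rate variability. Events live at frame centers: detection operates
at frame resolution, so ±half a frame (~32 ms) is the intrinsic
localization precision, and no waveform-level re-centering is attempted
(no clean fetal waveform exists at inference time).

## Heart rate and FHRE

Instantaneous heart rate is `HR = 60 / RR` (RR in seconds). The windowed
series assigns each interval to the 10-s window containing its midpoint and
averages the instantaneous HR per window; windows without intervals are
undefined (NaN). 10-s non-overlapping windows follow clinical convention.

FHRE then removes artifacts: **SD-ROM** ranks the four neighbours
{x(n−2), x(n−1), x(n+1), x(n+2)} as r₁ ≤ … ≤ r₄, computes
ROM = (r₂+r₃)/2 and the rank-ordered differences d₁, d₂ (distances of x
from the extreme and mid ranks on its side of the ROM), and replaces x by
the ROM when d₁ > T₁ or d₂ > T₂ (defaults T = (8, 20) bpm). Edge samples
pass through. The subsequent smoother is first-order exponential,
`y_n = α·x_n + (1−α)·y_{n−1}` with α = 0.3 — the specific filter type
matters little for this role, and α = 1 recovers the identity.

## Validation machinery

Frame-level accuracy is the primary metric (Class 1 vs Class 0 per frame);
beat-level matching (a detected event within ±50 ms of a reference peak,
greedy one-to-one) is a secondary metric for HR validation. Confusion
counts, sensitivity, PPV, NPV and F1 are computed directly; ROC/AUC via
trapezoidal integration over all thresholds; Pearson r with the
t-transform p-value; Bland–Altman bias and limits of agreement
`bias ± 1.96·SD` with the sample SD (n−1). k-fold splits are built from
contiguous frame blocks shuffled with a fixed seed (block ≈ 50 frames, at
least one block per fold); leave-one-subject-out trains on all other
subjects' frames. Printed-table reproduction uses round-half-even at the
printed precision, with float noise stripped at six guard digits first.

The published validation summaries (five-fold accuracies, the 26-subject
demographics table with leave-one-subject-out accuracies) ship in
`clinical_reference` so the summary arithmetic — fold means, cohort mean ±
sample SD (88.8 ± 6.4), gestational-age strata (28–34 weeks → 86.7%,
> 34 → 93%, < 30 → 88%) and the no-maternal-condition stratum (91%) — can
be recomputed without the confidential recordings. "No condition" means a
status of normal/none; sample SD uses the n−1 denominator, which is what
reproduces the printed 6.4 exactly.

## Problem sizes and defaults of the shipped experiment

`PipelineConfig` defaults define the package's reference experiment:
6 subjects × 60 s at 1 kHz, amplitude ratio 0.3, noise (0.1, 0.05, 0.1),
train 15 epochs on 5 subjects with hidden sizes (64, 32, 16), dropout 0.2,
Adam at 2·10⁻³ (dropping to 2·10⁻⁴ after epoch 8), batch 32, and evaluate
on the held-out subject. Three ensemble members are trained with different
initialization/shuffle seeds and their posteriors averaged: single short
training runs vary considerably from seed to seed, and the ensemble
average damps that variance at a proportional training cost. The reduced network and epoch count keep a full
run in the single-digit minutes on one CPU; the full-scale (200, 100, 50)
architecture is exposed through `DetectorConfig` and used for the
dimensional checks. The global seed fans out to per-stage seeds as
`(seed·1009 + stage_index) mod 2³¹−1`.

## Known limitations

* Synthetic-only validation; none of the simulator's omissions above are
  compensated elsewhere.
* Frame-resolution peak localization bounds HR precision; beat-to-beat
  variability measures (HRV) are out of scope.
* The FECGPP mechanics (refractory + median gap fill) are one admissible
  realization of the stated goal — fewer false detections at higher
  sensitivity; thresholds are exposed as configuration.
* The k-fold construction (contiguous blocks) is one defensible choice;
  subject-stratified alternatives would change fold composition.
* With very small training cohorts the classifier's generalization depends
  on the polarity augmentation; disabling it degrades unseen-subject
  performance sharply.
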