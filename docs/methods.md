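# Methods

`wavesick` re-implements, as a tested pipeline, an analysis workflow for
motion sickness (MS) induced on a VR wave platform: subjects stand on a
motion platform synchronized with a virtual sea, under three protocols
(static 60-s baseline P0; 120-s wave protocols P1 at 1 Hz and P3 at
3 Hz, each in four 30-s segments with platform amplitude 25/50/75/25 %),
while 64-channel EEG (500 Hz), bilateral gastrocnemius surface EMG
(1600 Hz) and heart rate are recorded; after each protocol the subject
scores 13 MS symptoms on a 0-2 scale.  Because no raw recordings are
publicly deposited, the package ships a synthetic-cohort generator with
known ground truth; every downstream claim the test suite makes is a
property of the method, demonstrated on that generator.

## Feature extraction

Nineteen parameters per measurement:

* **EMG (12)** — each leg's signal is band-passed with a 51-tap
  (50th-order) Hamming-windowed FIR at 40-500 Hz, applied with the
  group delay compensated.  The *area* is the mean rectified amplitude
  (integral of |x| / sample count, in uV).  Relative PSD is computed by
  periodogram over the whole trace in five equal bands (40-132,
  132-224, 224-316, 316-408, 408-500 Hz), normalised by the power over
  the union of the bands so the five shares sum to 1.  A note on the
  filter: at 51 taps the transition band is wide (~100 Hz at
  fs = 1600), so DC is attenuated to about |H(0)| = 0.065 rather than
  "removed"; tests assert against the filter's own frequency response,
  not an idealised brick wall.  With nonstandard rates the upper cutoff
  is clipped to 0.99x Nyquist to keep the operation reusable.
* **EEG (5)** — common-average reference; zero-phase band-pass
  0.1-40 Hz (2nd-order Butterworth run forward-backward, i.e. effective
  4th order — the method is not dictated by the workflow being
  reproduced, and a zero-phase IIR is standard EEG practice and cheap);
  channels whose absolute voltage ever exceeds 300 uV are marked bad;
  if more than 20 % of channels are bad the whole trial is rejected (a
  typed result — downstream stages keep the row with the five EEG
  features missing); otherwise bad channels are reconstructed by
  inverse-distance-weighted interpolation of the four nearest
  neighbours on a standard 10-10 position table (shipped as a small CSV
  fixture); per-channel offsets estimated from the subject's
  common-average-referenced static (P0) recording are subtracted
  (baseline correction read as offset subtraction; a PSD-ratio reading
  is conceivable but not implemented); the signal is cut into
  consecutive 30-s epochs and any epoch still exceeding 300 uV on a
  kept channel is dropped — an automated stand-in for manual visual
  artifact inspection, chosen for reproducibility.  Per epoch and
  channel, Welch PSD (2-s Hann windows, 50 % overlap — at least 1-Hz
  resolution for the 0.5-Hz delta edge while averaging ~29 segments per
  epoch) yields relative powers for delta 0.5-4, theta 4-8, alpha 8-13,
  beta 13-35 and low gamma 35-40 Hz, normalised over those five bands;
  shares are averaged over channels, then epochs.
* **HR (2)** — mean and sample (n-1) standard deviation of the
  beats/min series.  The chest sensor's internal 1 kHz sampling is
  irrelevant to these two statistics, so HR is carried as a 1-Hz
  beats/min trace.

Open choices resolved here: EMG relative PSD is computed on the whole
120-s trace (not per segment); relative-power denominators are the
named bands' union, which is what makes "relative" well defined.

## Symptom indexes

Eight binary indexes per cohort.  Group scalars: the direct responses
for general discomfort and dizziness/vertigo; group means for
stomach-related (stomach awareness, sweating, nausea, salivation,
burping), head-related (headache, fullness of head, blurred vision),
fatigue-related (fatigue, eye strain, difficulty focusing); the
physiological/vegetative group (stomach five + general discomfort) and
the neurological/muscle-strain group (fatigue three + head three +
general discomfort); and the weighted sum

    SumMS = 0.2*GenDis + 0.2*Dizz + 0.2*sum(stomach five)
            + 0.2*sum(fatigue three) + 0.2*sum(head three)

whose maximum (all answers 2) is 5.2.  Each scalar is binarised
cohort-relatively at one third of the cohort maximum.  Conventions: a
value exactly at the threshold is labelled 1 (a symptomatic tie should
not be labelled asymptomatic; the printed integer worked examples are
insensitive to this, and the rule is switchable); an all-zero cohort is
all-0; binarisation pools all measurements of the dataset (a
per-protocol or frozen-threshold mode exists for scoring new data
against a reference cohort).  Binarisation is invariant to positive
rescaling and cohort duplication, and monotone: raising one
measurement's symptoms can only demote another by raising the maximum.

## Screening

Every feature x index pair is tested with a two-sided Mann-Whitney U
(midranks).  Small samples (minority group <= 8 and at most 2x10^5
labelings) use tie-aware exact enumeration of all assignments;
otherwise the normal approximation with tie and continuity corrections
(via scipy).  Constant pooled data returns p = 1.  Stars follow the
strict convention * p<=0.05, ** p<=0.01, *** p<=0.001 on raw p-values
(no multiplicity correction drives the stars; a Benjamini-Hochberg
column is emitted alongside).  Printed tables floor p at 0.001.

## Classifier benchmark

Six families with fixed, documented defaults: random forest and
AdaBoost use the information-gain (entropy) split criterion — the
closest available analogue of the gain-ratio criterion named in the
original workflow, which scikit-learn does not implement — with 100
estimators; gradient boosting with 100 estimators; RBF SVM and
5-nearest-neighbours on standardised features; MLP with one hidden
layer of 32 units and early stopping.  Evaluation: stratified 10-fold
cross-validation repeated over 10 seeds (stratification keeps both
classes in every fold at n = 83; plain k-fold can be degenerate there).
Out-of-fold hard predictions and continuous scores (decision-function
values for the SVM, class-1 probabilities elsewhere) are pooled within
each seed; accuracy, sensitivity and specificity (class 1 =
symptomatic) are percentages, AUCROC lives in [0, 1]; means and SDs are
taken across seeds.  Rows with missing EEG features are dropped
listwise and counted in the manifest.  Subjects' three measurements are
*not* grouped into common folds (matching the plain k-fold evaluated
here); grouped CV would be the statistically safer variant for
subject-level generalisation claims.  Feature relevance is the mean
impurity-decrease importance over every random forest fitted on the
seeds' training folds, normalised to sum to 100 % — note that with
feature subsampling (`max_features='sqrt'`) duplicated columns gain
combined importance from increased availability; the split-sharing
property is exact only with subsampling disabled.

## Synthetic cohorts

The generator reproduces the study layout — n subjects x 3 protocols,
by default with the last subject missing P3, so 28 subjects give
(28 x 3) - 1 = 83 measurements — and couples everything through a
scalar stimulus intensity = wave frequency x mean platform fraction
(0, 0.4375, 1.3125 for P0/P1/P3; the product is the simulator's own
construct, ranking 3 Hz above 1 Hz).  Per subject, independent latent
traits: susceptibility ~ U(0,1), HR baseline ~ N(70, 8) bpm, EMG tone
~ 30*LogNormal(0, 0.25) uV, baseline beta gain ~ LogNormal(0, 0.2).

* **EEG**: frequency-domain synthesis of pink background plus five
  oscillators (delta 2 Hz, theta 6, alpha 10, beta 21 +- 6, low gamma
  37.5), calibrated to 15 uV RMS; beta amplitude is scaled by
  (1 + eeg_beta_effect * susceptibility * intensity).  Each band's
  power carries per-measurement LogNormal(0, 0.4) jitter emulating the
  large trial-to-trial variability of dry-electrode recordings —
  without it, channel-averaged Welch shares are so stable that even a
  tiny beta shift (and, through share normalisation, every other band)
  becomes overwhelmingly significant, which no noisy dry-EEG study
  shows.
* **EMG**: per 30-s segment, spectrally shaped Gaussian noise on
  40-500 Hz; with s = platform_fraction * (1 + emg_amp_effect *
  susceptibility), the RMS is tone * (1 + s) (times LogNormal(0, 0.15)
  per-leg jitter) and the 40-132 Hz band gets extra weight 1 + 0.6 s.
* **HR**: baseline + hr_effect * susceptibility * intensity + AR(1)
  drift (coefficient 0.9, innovation SD 1.5 bpm).
* **Questionnaire**: ordinal threshold model — each symptom's score
  counts the cut points (default (0.35, 0.90); higher for the rare
  vegetative symptoms salivation and burping) lying below
  g = symptom_gain * susceptibility * intensity plus N(0, 0.3) noise.

Presets: `strong` (emg 2.0, hr 20 bpm, eeg-beta 0.3, symptom noise
0.25), `weak` (0.6, 6, 0.15), `null` (all effects 0 **and**
symptom_gain 0).  The null must sever the questionnaire from the
protocol as well as from the latent state: platform movement raises EMG
amplitude by construction, so any protocol-driven symptom component
would confound features and indexes even with all signal effects at
zero.  Effect sizes are not reported by any study at this granularity;
the strong preset is calibrated to reproduce the qualitative pattern
the paradigm reports — EMG features dominating both the screening table
and the importance ranking, EEG weak with beta the most relevant band,
HR average in between — not any particular p-value or accuracy.
Randomness flows from one integer seed through a hierarchical
`SeedSequence` (subject -> protocol -> modality/questionnaire), so
identical configs are bit-identical and cohorts are stable under
partial regeneration.

What the generator does **not** emulate: volume conduction and electrode
geometry (channels are i.i.d.), true EMG nonstationarity within
segments, HR/respiration structure, learning or habituation across
protocols, and any VR/vection mechanism.  Passing tests therefore show
that the pipeline recovers couplings of this statistical form — not
that it would reproduce any particular empirical effect on real data.

## Problem sizes used in the test suite

Chosen as the package's own benchmark conditions: the study-sized
cohort is 28 subjects (83 measurements); null calibration pools 500
Mann-Whitney p-values from 20 independent null cohorts of 10 subjects
(25 randomly sampled feature x index cells per cohort, only cells with
both groups >= 5, normal-approximation mode) and checks uniformity with
a Kolmogorov-Smirnov test at alpha = 0.01 — cells within a cohort are
weakly dependent, cohorts are independent; recovery uses a 200-subject
full-grid strong-preset cohort (600 measurements) on which the random
forest must reach AUCROC >= 0.80 for the overall MS index and EMG
features must dominate the importance ranking.  All stochastic tests
run with fixed seeds.

## Known limitations

* The exact Mann-Whitney path enumerates assignments only while the
  count is tractable (<= 2x10^5); beyond that the tie-corrected normal
  approximation is used even for minority groups of <= 8.
* EDF output is not provided; recordings are written as CSV with a JSON
  sidecar (rate, labels), which round-trips exactly but is bulky —
  full-size EEG is ~45 MB per measurement, so recording export is
  off by default in the pipeline and on demand in the CLI.
* The gain-ratio split criterion is approximated by information gain.
* `cohort_binarize` thresholds are cohort-relative; scores for a single
  new measurement are meaningless without a reference cohort.
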