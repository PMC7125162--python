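# Methods

This note documents the models, parameters and design choices behind
`wristmotor`, and what the synthetic experiments do and do not demonstrate.

## The cohort simulator

The simulator produces the *shape* of clinical wrist-accelerometer data —
not its clinical content.  Each subject gets a session of configurable
length; the per-minute motor state follows a row-stochastic Markov chain
over {OFF, ON, DYS}.  The default chain uses the reversible construction
P[i,j] = 0.1·π[j] (i ≠ j), which makes its stationary distribution exactly
π = (26.8 %, 41.4 %, 31.8 %) — a realistic minute mix for fluctuating
patients — with mean dwell times around 15 minutes.  Activities follow an
independent diagonal-heavy chain over
{sitting, lying, walking, standing, sleeping, testing, other}.

Within a minute, the acceleration signal is a sum of amplitude-modulated
sinusoids with random orientation, random phase, and per-minute frequency
jitter:

| state | content | defaults |
|---|---|---|
| OFF | low voluntary movement + intermittent rest tremor | 0.10 G in 0.5–3 Hz; 0.25 G bursts in 4–6 Hz, active ~70 % of seconds |
| ON | moderate voluntary movement | 0.30 G across three 0.5–3 Hz components |
| DYS | high-amplitude irregular oscillation | 0.60 G in 1–4 Hz with slow amplitude modulation |

Walking adds a gait harmonic (≈1.9 Hz plus its octave, 0.25 G).  A 1 G
gravity vector performs a slow orientation random walk (0.02 rad/√s) and is
later removed by the 0.1 Hz high-pass edge of the filter; white sensor noise
(0.02 G) and ±8 G clipping complete the model.  Sampling is nominally
62.5 Hz with ±2 % uniform jitter per interval, which forces the resampler
to do real interpolation.  Severity items are coupled to the state by a
fixed monotone map plus bounded integer noise (bradykinesia 3/1/0 for
OFF/ON/DYS; dyskinesia 0 outside DYS, ≥1 inside), so correlation analyses
have a recoverable ground truth.  Dropout minutes produce no samples;
unannotated minutes are recorded but carry no motor state.

These signatures were chosen once as plausible band-limited stand-ins with
amplitudes that clear the 0.01 G² variance floor the preprocessing applies;
no claim of clinical realism is made.  In particular the simulator omits
sensor artefacts, broadband real-world activity spectra, inter-subject
signature variability beyond random phases/frequencies, and any non-motor
correlates.  Passing tests therefore demonstrate that the *pipeline*
recovers class structure that is genuinely present at realistic data shapes
and sizes — not that the classifier would reach any particular accuracy on
real patients.

## Preprocessing

Filtering precedes resampling, at each segment's native rate.  The filter
is a Butterworth band-pass, 0.1–20 Hz, order 4 per direction, applied
forward–backward (`sosfiltfilt`) for zero phase; the effective magnitude
response is the squared design response.  The order is a package choice
(the band edges are fixed requirements; the order is not specified by the
protocol the package reproduces): order 4 is a common default, steep enough
at 20 Hz without ringing, and a dedicated test documents that
filter-then-resample and resample-then-filter agree within 2 % RMS on
band-limited signals.  Contiguous segments are delimited by timestamp gaps
> 0.5 s; segments shorter than the filter's stable padding length are
dropped and logged.

Resampling is linear interpolation onto the *global* k/60 s grid, so
windows from different segments stay mutually aligned.  Minute k covers
[60k, 60(k+1)) seconds, half-open, 0-based.  A minute is kept only if all
3600 grid samples exist (otherwise logged `dropout`), a motor-state
annotation exists (`unannotated`), and the summed per-axis variance of the
filtered values reaches 0.01 G² (`low_variance`).  The variance check runs
on filtered 60 Hz data — the only representation the pipeline carries at
that point — and the threshold is a config knob.  Bookkeeping is exact:
kept + discarded = recorded minutes, per subject and overall.

## Augmentation

Sliding windows: only pairs of kept minutes whose start times differ by
exactly 60 s are slid (offsets 5, 10, …, 55 s; offsets 0/60 duplicate the
originals and are produced once), giving M + (M−1)·11 windows per gap-free
run — an asymptotic 12× factor.  Labels interpolate linearly, so training
targets can be fractional; a float label ℓ becomes a two-point probability
target with mass 1−frac(ℓ) on ⌊ℓ⌋ and frac(ℓ) on ⌈ℓ⌉.

Rotations are drawn uniformly from SO(3) (random unit quaternions) and
applied *in place*, one independent rotation per slid window, so rotation
does not multiply the sample count.  Both choices — the uniform
distribution and per-window application — are package decisions where the
protocol is silent; they maximize pose invariance and keep the expansion
factor at the observed ≈12×, and both are exposed as options
(`--no-rotation`, `--stride-seconds`).

Augmentation is training-only.  Feeding a designated test subject into
`augment_training_set` or `train_member` raises `LeakageError`.

## The classifier

Seven convolutional blocks (conv → batch-norm → ReLU), valid padding, with
temporal (kernel, stride) schedule (8,4), (8,4), (5,3), (4,2), (4,2),
(3,1), (2,1): lengths 3600 → 899 → 223 → 73 → 35 → 16 → 14 → 13.  The two
published descriptions of the channel schedule contradict each other; both
ship as named configs.  The default `caption` schedule
[8, 16, 16, 32, 32, 64, 64] is the self-consistent one (13·64 = 832
flatten); `paper-text` [64, …, 1024] flattens to 13·1024; `reduced`
[4, 8, 8, 16, 16, 32, 32] exists for desk-scale runs.  Which schedule the
original deployed network used is unknowable; neither is claimed to be
"the" original.

The three axes enter as input channels of a 1-D convolution.  The
alternative single-channel 2-D "image" layout with a width-3 kernel in
block 1 collapses the width dimension immediately and is arithmetically
identical; both layout names map to the same computation (verified by a
test).

Training specifics are unreported in the protocol and are package choices,
all in `CNNConfig`: Adam (lr 1e-3), soft-label cross-entropy, batch 64,
optional early stopping on one held-out training subject (patience 2) when
a member's subset has ≥ 4 subjects.  Convolutions carry no bias (batch-norm
absorbs it).  Because desk-scale trainings take few optimizer steps, the
batch-norm running statistics are recalibrated after training with one
exact pass over the training inputs; without this, inference-mode
normalization is biased toward its initialization.  Ensemble members train
on random subject subsets of size min(15, n_train); the default member
count is 5, and the ensemble prediction is the mean of member softmax
vectors (the aggregation rule is a package choice).  Categorical prediction
is the argmax, ties broken toward the lower class index (conservative
toward OFF).

## Postprocessing

expCNN = 0·p(OFF) + 1·p(ON) + 2·p(DYS) is an ordinal score in [0, 2]; it
measures adherence to the trained model, not symptom severity.  Day curves
are LOESS-smoothed: tricube weights, span 0.25 of the segment, local
polynomials of degree 2 (classical defaults; both configurable), evaluated
at the input times and clipped to [0, 2].  Smoothing never bridges gaps
longer than 10 minutes — recording outages remain visible as breaks — and
segments with fewer than degree + 2 points pass through unsmoothed.
Subject summaries use the population SD (divide by n), consistently.

## Evaluation

LOSO folds exactly partition the subjects; scoring uses each fold's
original (non-slid, non-rotated) test windows whose labels are integers —
the rater's annotation is the reference.  Scoring the augmented test set
instead is available via `score_augmented` for comparability with
evaluations that pooled augmented windows.  The metric battery: one-vs-all
sensitivity, specificity, PPV, NPV, (sens+spec)/2, detection and true
prevalence per class; macro recall; Cohen's κ from the marginals.
Zero-denominator rates are reported as missing (NaN), never as 0.

For criterion validity, expCNN is mapped to the two item directions before
aggregation — brady = 1 − clip(expCNN, 0, 1), dys = clip(expCNN, 1, 2) − 1
— a package choice that realizes the "0 to 1 for bradykinesia, 1 to 2 for
dyskinesia" convention with positive expected correlations.  Window means
(1, 5, 30, 60 minutes; "daily" = the whole recording per subject) are
pooled across subjects for Pearson r with t-distribution p-values and
Fisher-z 95 % CIs; p-values are reported raw, with no multiple-testing
correction.  Correlations with fewer than 3 paired windows or zero variance
are missing.

ICC(2,1) — two-way random effects, absolute agreement, single rater — is
computed from the two-way ANOVA mean squares with the F statistic and the
standard F-based 95 % CI (Satterthwaite df); `pingouin` serves as an
independent oracle in the tests.  Committee votes use the mode of the three
specialist ratings, with a three-way tie resolved by the median.

Baselines (linear SVM, kNN with n = 10, random forest, MLP) consume the
flattened 10,800-value raw window under grouped 4-fold CV on non-augmented
windows.  The scale-sensitive models (SVM, MLP) are preceded by a
standardizer — still raw samples, no feature extraction.  On the default
simulator their balanced accuracies sit near chance while the CNN recovers
the classes, reproducing the qualitative gap the approach is known for.

## Problem sizes and numerical choices

The desk-scale experiment (the `demo` subcommand and the acceptance script)
uses 8 subjects × 45 minutes, the `reduced` channel schedule, 4 epochs and
a single ensemble member per fold — sizes chosen so the full LOSO loop runs
in about a minute on one CPU while leaving a wide margin over the ≥ 0.80
balanced-accuracy bar (chance 1/3).  One master seed derives per-stage
seeds by hashing `"<stage>:<seed>"` (CRC-32, < 2³¹), so stages draw from
disjoint reproducible streams and identical manifests yield byte-identical
reports.  Cohort CSVs are written with `%.17g` and parsed with
round-trip-exact float parsing, making `read(write(x)) == x` hold to full
precision.

## Known limitations

* The simulator's class signatures are stylized; absolute performance
  numbers on it say nothing quantitative about clinical accuracy.
* The numpy network targets the package's window/schedule family, not
  general architectures; there is no GPU path, which is sufficient at desk
  scale but not for channel schedules in the `paper-text` range on large
  cohorts.
* Only the accelerometer is modelled — no gyroscope, heart rate or galvanic
  channels — and no biomechanical realism (posture, limb geometry) is
  attempted.
* expCNN is ordinal; it is not calibrated to symptom severity, and no such
  claim is encoded anywhere in the package.
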