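# Methods

This note documents the models, parameters and numerical choices behind
`gazescreen`, and what its synthetic validation does and does not show.

## Synthetic reading cohorts

`simulate.simulate_recording` renders a reader's cyclopean trajectory
over an abstract multi-line text (default: 8 lines, 10 sentences of 4.6
words on average, 20° of horizontal extent, 1.5° line spacing; content,
word frequency and landing positions are deliberately not modelled).
The trajectory alternates fixations and saccades:

* **Fixation durations** are lognormal with group mean/SD (defaults:
  HR 280 ± 70 ms, LR 210 ± 50 ms), clipped to [60, 800] ms so every
  rendered fixation satisfies the detector's 50 ms stability criterion.
* **Progressive saccade amplitudes** are gamma with group mean/SD
  (HR 2.0 ± 0.8°, LR 3.0 ± 0.9°), clipped to [1.1°, 6°].
* **Regressions** occur with probability `regression_prob` per
  opportunity (HR 0.35, LR 0.15), with amplitudes drawn at 0.6× the
  progressive scale and clipped to [1.1°, 4.5°] — above the dispersion
  threshold, below the sweep rule.
* **Return sweeps** jump from the line end to the start of the next
  line (leftward ≈ line extent, downward one line spacing).

The group defaults encode the qualitative directions expected for
readers with decoding difficulty — longer fixations, shorter forward
saccades, more regressions — and are configuration, not claims about
any population. A per-subject lognormal jitter (`subject_cv`, default
8% CV) on the duration and amplitude means adds between-subject
heterogeneity; without it every subject of a group would be an i.i.d.
re-draw of the same process and classification would be degenerate by
construction.

**Saccade rendering and the detection oracle.** Saccades are rendered
as accelerating ramps of 1–3 interior samples depending on amplitude
(1 below 2.2°, 2 up to 7°, 3 beyond). At 100 Hz a saccade rarely spans
more than a few samples, and this profile has a useful exactness
property: every interior sample lies beyond the dispersion threshold of
the run it leaves or joins, while the landing sample falls within the
threshold of the in-flight run. Longer ramps cannot have this property
— the in-flight run's own RMS inflates the dynamic threshold faster
than a ramp's deviation grows — so with all noise sources disabled the
detector recovers the rendered event boundaries *exactly*, and the
generator doubles as an oracle for the detector (this is tested over
many seeds for both parameter sets).

**Binocular rendering.** The vergence offset is an AR(1) process
(lag-1 coefficient 0.9, stationary SD `vergence_noise_sd`, defaults
0.2–0.3°) applied symmetrically (±offset/2 per eye), so the version
signal equals the cyclopean trajectory exactly and vergence noise never
perturbs detection. White measurement noise (default SD 0.1°, in line
with arcminute-class goggle trackers) is added per eye and axis;
dropouts (default 1% of samples) invalidate both eyes; transient
artifacts (default 0.1/s) displace 2 samples inside long fixations by
2–4°, splitting the host fixation in the ground truth. Recordings are
capped at 60 s and truncated at an event boundary.

`generate_cohort` derives per-subject integer seeds from the cohort
seed via a `SeedSequence`, making cohorts byte-reproducible through the
text file round trip.

**Stimulus-text metrics.** `textmetrics` computes TTR, OVIX and OVR
from type/token counts with natural logarithms (the convention that
reproduces the published worked example 71.7% / 46 / 91.3% for 33 types
among 46 tokens). `n_type == n_token` makes the OVIX denominator
`log(1) = 0` and raises a domain error rather than a numeric exception.

## Event detection

The state machine runs on the version signal only; vergence is carried
along for feature computation. Defaults: dispersion base 0.5°
(roughly the foveal radius), noise multiplier 2.5, noise window 25
samples, minimum fixation 50 ms, sweep threshold 5°.

Numerical conventions, chosen where the procedure is under-specified:

* "RMS error of the last 25 samples" is the RMS deviation from the
  window mean (a stationary-noise estimate), computed over the last
  ≤ 25 samples *of the current run*, so the dynamic threshold resets at
  each state change. A window reaching back across a state change would
  let a just-finished saccade inflate the threshold and swallow the
  next one.
* Both axes must be within threshold for stability; exceedance on
  either axis starts a saccade. A sample exactly at the threshold
  counts as within. Fewer than 2 window samples give RMS 0.
* The stable-run mean is the mean of *all* samples in the current run
  (not only the window), and the run is not reset on promotion from
  transient to fixation.
* 50 ms at 100 Hz means a fixation needs 6 samples (inclusive
  first-to-last span ≥ 50 ms). Saccades have no minimum duration.
* Any sample unusable in the version signal (either eye invalid) is a
  distortion sample; a distortion interrupts the current run, which is
  emitted as-is, with no merging across the gap.
* A saccade's direction uses its takeoff-to-landing displacement (the
  nearest usable samples just outside the event), because a
  single-sample saccade has zero within-event displacement. The feature
  parameter D, by contrast, is the within-event signed span.

Recordings shorter than the minimum fixation emit a warning and no
events. Events always tile the sample range: every sample belongs to
exactly one event of exactly one kind.

## Features

Parameter 4 ("SD of the average position") is implemented as the SD of
the position samples within the event — the event's mean position is a
single number, so its dispersion must refer to within-event spread.
Population (not sample) SDs are used both within events and across
event pools, so single-event pools are well-defined. D is kept signed.
Sweeps, transients and distortions feed no feature pool, and fixations
with no preceding saccade (the first of a recording) are excluded from
the directional pools. Empty pools are zero-filled and flagged
per class (`empty_class_flags`) rather than emitted as missing values,
keeping the classifier input rectangular while staying auditable.

The canonical feature order is: event class (PF, RF, PS, RS); within a
class Dur first, then D, M, S, R, A by axis (hor, vert) and mode
(version, vergence); mean before sd. Ids like `PS.D.hor.version.mean`
parse back to their descriptor.

## Evaluation protocol

The SVM is `sklearn.svm.SVC(kernel="linear")` (libsvm's SMO) with
C = 1 — a standard SMO default — and training-fold z-scoring, which
makes squared-weight RFE ranking scale-invariant; both are
configuration. RFE removes exactly one feature per iteration; weight
ties are broken by removing the larger column index first, making the
ranking deterministic. Per-repetition metrics pool the 10 test folds'
predictions, then mean ± SD (sample SD) is taken over repetitions.
Stratified folds keep each fold's class ratio within one subject of the
cohort's. Y-randomization flips ⌊n_c/2⌋ labels per class in the
training fold only. The corrected resampled t-test uses the
train/test-overlap variance correction with `test_fraction = 1/folds`
and k − 1 degrees of freedom over the k = folds × repetitions paired
fold scores; two runs can only be compared when their resampling plans
(folds, repetitions, seed) coincide, so folds pair up.

Leakage is structurally impossible: scaling statistics, rankings and
random subsets are computed from training rows only, and the test fold
enters only at prediction time; tests assert each subject is tested
exactly once per repetition.

Default repetitions are 100 (the documented full protocol); the test
and acceptance suites run 10 repetitions and a reduced subset-size
grid, sizes chosen so the whole suite runs comfortably on one CPU.

## Feature analysis

Selection frequencies count, per feature, the internal training folds
whose top-n ranking contained it (n defaults to the best-accuracy
subset size). Quartiles use linear interpolation between order
statistics — published quartile styles may differ, so cross-study
comparison of printed quartiles is qualitative only. "Majority of
folds" means strictly more than folds × repetitions / 2. Min-max
normalization for group box plots is computed over both groups pooled;
per-group scaling would erase exactly the contrasts of interest. The
per-event-class share of majority-selected features is reported both as
share of feature count and as share of accumulated frequency, since
"percent related to" admits both readings.

## What the synthetic validation shows — and does not

Passing tests show that the detector recovers known event structure,
that the feature taxonomy and protocol behave correctly (chance-level
results on null and Y-randomized cohorts, RFE recovering planted
informative features, full-dimension RFE equalling a plain SVM), and
that the whole pipeline is deterministic under fixed seeds. They do
*not* show that real HR/LR cohorts are separable at any particular
accuracy: the generator's group contrasts are stylized, its default
effect sizes make the synthetic groups close to perfectly separable at
the study's sample size, and real recordings contain structure (lexical
effects, calibration drift, head movement, individual strategies) the
generator deliberately omits. Accuracy numbers on synthetic cohorts
characterize the pipeline, not any clinical population. Chance-level
checks are calibrated at the full cohort size (n = 185); on much
smaller null cohorts, cross-validated accuracy can drift far from 50%
simply because idiosyncratic sampling differences between the groups
are learnable.

## Known limitations

* The detector is dispersion-based by design; no velocity-based (I-VT)
  or probabilistic segmentation, no blink model beyond distortions.
* Detection runs on the cyclopean signal; per-eye detection is not
  implemented.
* The SVM's cost, scaling and solver tolerances are fixed by
  configuration, not tuned; results on real data could shift with them.
* The generator abstracts the stimulus to line geometry; no word-based
  measures exist anywhere in the pipeline (by design).
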