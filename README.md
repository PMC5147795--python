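# gazescreen

Screening for persistent reading difficulty from eye movements during
reading. `gazescreen` implements, as a tested and reusable pipeline, the
analysis behind eye-tracking-based dyslexia screening: detect
eye-movement events in binocular gaze recordings of text reading with a
dynamic dispersion-threshold state machine, describe each reader by a
fixed 168-feature summary of their fixations and saccades, and estimate
how well high-risk (HR) readers can be told apart from low-risk (LR)
readers with a linear SVM under a repeated, internally nested
cross-validation protocol with SVM-RFE feature selection,
Y-randomization and random-feature baselines.

It is aimed at researchers in reading, oculomotor control and screening
methodology who want to reproduce, stress-test or extend this kind of
analysis. Because the original clinical recordings are not public, the
package ships a first-class synthetic-cohort generator that emulates
8-line silent-reading recordings at 100 Hz with group-conditional
fixation durations, saccade amplitudes and regression rates, plus
measurement noise, signal dropouts and transient artifacts — with exact
ground-truth event lists, so the detector can be validated against a
known answer.

## The method in brief

**Event detection.** The version (cyclopean) signal
$v = (\mathrm{left}+\mathrm{right})/2$ is walked sample by sample through
four mutually exclusive states — *distortion* (signal lost), *transient*
(stable, but briefly), *fixation* (stable for ≥ 50 ms) and *saccade*.
A sample is stable when both axes lie within
$T = 0.5^\circ + 2.5 \times \mathrm{RMS}_{25}$ of the running mean of the
current state's samples, where $\mathrm{RMS}_{25}$ is the RMS noise of
the last 25 samples of the current run. Large leftward movements
(≥ 5°) are return sweeps; other saccades are progressive (rightward) or
regressive (leftward), and fixations inherit the direction of the
preceding saccade.

**Features.** Events are pooled into progressive/regressive fixations
and saccades (PF, RF, PS, RS). Each event is measured by its duration
and by five spatial parameters (spanning distance D, mean position M,
positional SD S, maximum range R, accumulated distance A) on each of
four signals: horizontal/vertical × version/vergence
($\mathrm{vergence} = \mathrm{left}-\mathrm{right}$). Mean and SD of
each parameter over the events of a pool give
$4 \times (1 + 5\cdot2\cdot2) \times 2 = 168$ features per subject.

**Evaluation.** 10-fold stratified cross-validation repeated (by
default) 100 times; inside every training fold the features are
z-scored and ranked by SVM-RFE (repeatedly fit a linear SVM, drop the
feature with the smallest squared weight), and classifiers over a grid
of subset sizes predict the untouched test fold. Accuracy, sensitivity
(HR identified) and specificity (LR excluded) are reported as
mean ± SD over repetitions. Chance level comes from Y-randomization
(half of each class in the training fold swaps labels); selection
quality is benchmarked against uniformly random subsets; curves are
compared with the variance-corrected resampled t-test
$t = \bar d \,/\, \sqrt{(1/k + \tfrac{r}{1-r})\,\hat\sigma^2_d}$ with
$r = 1/\text{folds}$.

## Worked example

```python
import gazescreen as gs
from gazescreen.evaluate import ProtocolConfig

spec = gs.CohortSpec(n_hr=30, n_lr=30, seed=42)     # synthetic HR/LR cohort
cohort = gs.generate_cohort(spec)

events = gs.detect_events(cohort[0])
print(f"{cohort[0].subject_id}: {len(events)} events, "
      f"{sum(e.kind == 'fixation' for e in events)} fixations, "
      f"{sum(e.kind == 'saccade' for e in events)} saccades")

table = gs.cohort_feature_table(cohort)             # 60 x 168 + label
result = gs.run_protocol(
    table,
    protocol=ProtocolConfig(repetitions=10, fs_method="rfe",
                            n_features_grid=(8, 32, 168), seed=7),
)
print(result.curve()[["accuracy_mean", "accuracy_sd"]])

freq = gs.selection_frequencies(result, gs.feature_schema(), n=8)
print(freq.sort_values(ascending=False).head(5))
```

prints

```
HR001: 518 events, 228 fixations, 192 saccades
            accuracy_mean  accuracy_sd
n_features
8                   100.0          0.0
32                  100.0          0.0
168                 100.0          0.0
PF.S.vert.vergence.mean    99
PS.D.hor.version.mean      86
PS.M.hor.vergence.sd       84
PF.S.hor.vergence.mean     74
RF.S.vert.vergence.mean    63
Name: selection_count, dtype: int64
```

The first line summarizes one detected recording (an HR reader: many,
long fixations). The curve shows cross-validated accuracy by feature
subset size — the default synthetic effect sizes separate the groups
essentially perfectly, so accuracy saturates; with a null cohort
(identical group parameters) the same protocol returns chance (~50%).
The last block lists how often each feature was selected across the
10 × 10 internal training folds at subset size 8: fixation-duration and
progressive-saccade-amplitude features dominate, mirroring the
generator's group contrasts.

The same pipeline is scriptable from the shell:

```bash
gazescreen full --config config.yaml --out run_dir --seed 7
```

which writes the gaze files, events, feature matrix, protocol result
and feature analysis (plus optional plots) into `run_dir/` with every
stage seeded and logged.

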