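# Methods

This note documents the models and procedures implemented in `stroopgaze`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic cohorts can and cannot show about real recordings.

## Experimental structure assumed

One trial is one subject viewing one 4×4 word grid (sixteen areas of
interest tiling a 1024×768 px canvas) under one of four conditions —
Reading or Naming, each With or Without colour–word interference (RWoI,
RWI, NWoI, NWI).  A trial begins after the subject has dwelt ≥ 100 ms on a
trigger dot at the top-left and ends with a key press.  The unit of
analysis is the (subject, condition) pair: each contributes one row of 29
oculomotor variables.

Coordinates are screen pixels, origin top-left, y downward; times are
milliseconds from trial onset.  Conversions to degrees of visual angle use
a viewing-geometry configuration (`ViewingGeometry`): screen width 376 mm
at 1920 px, eye distance 490 mm (midpoint of the 46–52 cm seating range),
giving ≈ 0.023°/px at screen centre.  The full `2·atan(d/2D)` formula is
used, so large distances are not linearised.

## Cleaning cascade

Stages run in a fixed order — head, tail, AOI, duration — so that the
time-window cuts precede the statistical duration filter and the z-sample
reflects task-period fixations only:

1. **trim_head** — drop every event starting before `trigger_end`.
2. **trim_tail(k)** — drop the last `k = 5` fixations and saccades starting
   after the new last fixation; these cover the span between the last word
   and the key press.
3. **filter_offgrid** — drop fixations outside every AOI cell.  Cells tile
   the canvas, so with the default `aoi_margin_px = 0` only off-canvas
   fixations are removed; the margin is configurable because no distance
   threshold for "well outside" is defined.
4. **filter_duration** — drop fixations shorter than `min_fixation_ms`
   (default 200; the floor is inclusive, a 200 ms fixation survives), then
   drop fixations whose duration z-score is ≥ `z_max` (default 3).  The z
   statistics use the sample (n−1) standard deviation over the fixations
   surviving the floor, computed per trial by default (`z_scope` can widen
   the sample to the subject or the whole cohort).  The filter is
   single-pass: statistics are not recomputed after removals
   (`iterative_z` enables re-iteration).  A scope of fewer than two values
   or zero spread keeps everything.

`trim_head` and `filter_offgrid` are fixed points (applying them twice
changes nothing).  `trim_tail` by definition removes `k` more fixations on
every application, and a one-pass z-filter may flag new outliers if
reapplied (the survivor sample has a smaller spread), so the cascade is
designed to run exactly once per trial; the test suite checks exactly
these properties rather than blanket idempotence.

## The 29 variables

**Fixation block (7).**  `n_fix`; `fix_mean` / `fix_max` = mean / max
duration (ms); `norm_fix_mean` / `norm_fix_max` = the same divided by the
active viewing time (first fixation onset to last fixation end after
cleaning).  The normalised pair removes the trivial dependence of duration
statistics on how long the subject took overall.  `x_regressions` counts
consecutive fixation pairs whose x decreases while the grid row is
unchanged — row changes are excluded so that the return sweep to the start
of the next line is not counted as a regression; `y_regressions` counts
pairs whose y decreases (an upward step).  The vertical count has no
exclusion clause: an upward movement is always against the top-to-bottom
reading order.

**Saccade block (22).**  Direction frequencies use a dominant-axis rule
(|Δx| ≥ |Δy| → left/right by sign of Δx, ties to horizontal; otherwise
up/down by sign of Δy), normalised by the number of nonzero-displacement
saccades, so the four frequencies sum to 1.  Six min/avg/max triples cover:
duration (ms) and velocity (deg/s) and amplitude (deg) as reported by the
tracker; angle = `atan2(−Δy, Δx)` in degrees, range (−180, 180], upward
positive; distance = Euclidean start→end displacement converted to degrees;
slope = Δy/Δx, with vertical saccades mapped to ±10⁶ (sign of Δy) to keep
the order statistics finite.

A trial with no surviving fixations reports `n_fix = 0` and NaN elsewhere;
no saccades gives NaN for the whole saccade block.  NaN rows are excluded
feature-wise from the ANOVA and imputed with the training-fold median in
classification, which avoids any test-fold information entering the fit.

## Normalization

`subject_center` subtracts, per subject and per feature, the mean over that
subject's conditions.  It uses only the subject's own rows — never another
subject's labels — so it is applied once, before any cross-validation
split, as a dataset-preparation step.  Min–max scaling to [0,1] is fitted
on training-fold rows only and applied to held-out rows, which may then
leave [0,1] (clipping is available but off by default); a constant training
feature maps to 0.  Fold-local fitting is the leakage-safe default; a
global mode exists for comparison, as does z-scoring.

## ANOVA screen

Each of the 29 variables is compared between the two groups of a contrast
with a standard one-way ANOVA (`scipy.stats.f_oneway`).  With two groups
F = t² and the p-value equals the two-sided equal-variance t-test — the
test suite verifies this identity against an independent t-test route on
1000 random datasets.  Contrasts: NWoI vs RWoI (control), NWI vs NWoI,
RWI vs RWoI, and pooled Naming vs Reading.  Raw per-feature p-values are
reported with stars at 0.05/0.01/0.005; Benjamini–Hochberg adjustment is
available but off by default, matching the raw-p presentation style.  The
ANOVA runs on the uncentered, unscaled table, since normalization belongs
to the classification branch.  The design is within-subject but the screen
deliberately uses a plain between-group ANOVA rather than a
repeated-measures model; this replicates the screening procedure as
specified and is a known statistical simplification.

## Classification

Three binary tasks (NWoI vs RWoI, NWI vs NWoI, RWI vs RWoI) × four feature
sets (Fix = 7, Saccades = 22, Fix+Saccades = 29, Fix+Saccades-norm = 29
after subject centering) × four classifiers, each under stratified 5-fold
cross-validation with a single seed controlling the split and the
classifier randomness.  Per fold: impute NaN with training medians, fit the
min–max scaler on training rows, fit the classifier, score Accuracy and
binary F1 (positive class = first-named condition) on the held-out rows.
Rows are split individually; the same subject can appear in both classes
(one row per condition), and a subject-grouped split mode exists for
methodological comparison.

Hyperparameters (fixed, exposed in `make_classifier`): RF = 100
bootstrapped trees; Logistic = L2, C = 1; ANN = one hidden layer of 32
units, Adam with learning rate 0.01 and early-stopping patience of 25
epochs (both sized for ~100-row training folds, where the library defaults
stop before learning), at most 1000 epochs; SVM = RBF, C = 1, gamma scaled
to feature count.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
not photorealistic gaze.  A trial is built from:

- **Head**: 1–2 trigger fixations at the top-left totalling
  `head_dwell_ms` (default 150 ms, protocol minimum 100 ms).
- **Walk**: the gaze visits the 16 cells in reading order.  At each word it
  refixates with probability `p_refixate` (geometric repeats), makes a
  one-word backward excursion within the row with `p_regress_x`, and a
  one-row upward excursion with `p_regress_y`; each excursion returns
  immediately, mirroring the re-read-and-continue pattern of regressive
  eye movements and guaranteeing termination with a path length linear in
  the grid size.  Fixation positions are cell centres plus Gaussian jitter
  (sd 14 px, clipped to the cell).
- **Durations**: log-normal per condition (median `fix_median_ms`, log-sd
  `fix_sigma`), times a per-subject log-normal factor (sd 0.15).
- **Noise**: after each walk fixation, with probability `offgrid_rate`
  (default 0.05) a short off-canvas fixation is injected; after the last
  word, 5 tail fixations are appended.  These exist so the cleaning
  cascade has something real to remove.
- **Saccades** connect consecutive fixations with endpoints exactly at the
  flanking fixation coordinates; duration is normal
  (`sacc_dur_mean_ms` ± 8 ms, per-subject factor sd 0.15, floor 8 ms),
  amplitude is the start→end distance in degrees, velocity its mean speed.

Per-subject random effects (duration factor, logit-scale shift on the walk
probabilities, saccade-duration factor) are drawn reproducibly from the
cohort seed and create the strong inter-subject variability that motivates
subject-wise centering.

**Frozen condition effects** (`calibrate_defaults`): fixation-duration
medians 230/250/290/340 ms and walk probabilities rising from RWoI through
RWI and NWoI to NWI, saccade-duration means 30/32/34/38 ms.  The ordering
encodes the qualitative picture — naming is slower and more effortful than
reading, interference adds strongly to naming and only weakly to reading —
and the magnitudes were calibrated once so that the fixation block
separates the contrasts sharply while the saccade block separates weakly,
and classification sits above chance everywhere with the best cells above
0.8; they are frozen thereafter.  No per-condition descriptive statistics
exist to anchor them quantitatively, so they are qualitative calibrations,
documented as such.  `null_config` gives all four conditions identical
parameters (subject effects remain) for calibration runs: the ANOVA
p-values are then uniform and classifiers sit at chance.

## Calibration facts worth knowing

- On zero-effect cohorts the replicate-averaged CV accuracy is slightly
  *below* 0.5 (≈ 0.47): cross-validation at chance level is pessimistically
  biased, and here each subject contributes one row per class, so a
  classifier keying on subject-specific noise finds the held-out twin row
  carrying the opposite label.  This is a property of the evaluation
  design, not a bug; the acceptance check averages 20 replicate cohorts
  so the estimate is stable (SE ≈ 0.01).
- After cleaning a default-effect cohort, per-trial maximum fixation
  durations fall mostly in the high hundreds of ms — the regime the
  z-retention rule is meant to preserve rather than truncate.

## Problem sizes

Default cohorts are 64 subjects × 4 conditions (≈ 30 fixations per raw
trial).  The test suite uses 25–32-subject cohorts for oracle and grid
checks, 50 replicate 64-subject cohorts for the ANOVA power check, 20
replicate cohorts for the chance-level check, and 2000 independent
two-group draws (8 trials per group) for the type-I calibration — sizes
chosen so the whole suite runs in a couple of minutes while keeping
Monte-Carlo error well inside the asserted bands.

## Limitations

- The simulator models neither 500 Hz sample-level gaze, blinks,
  microsaccades, pupil size, saliency-driven exploration, nor word-level
  linguistic effects; passing tests demonstrate that the *analysis chain*
  is correct and calibrated, not that real recordings will reach the same
  classification accuracies.
- Condition effect sizes are qualitative calibrations; absolute p-values
  and accuracies on synthetic cohorts are not predictions for real data.
- The ANOVA ignores the within-subject design (see above).
- Only fixations are filtered by the duration/z rules; saccades are cut
  only by the head/tail window, and whether saccades attached to removed
  fixations should also be removed is left open.
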