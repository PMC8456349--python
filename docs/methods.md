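# Methods

## The prediction problem

A maintenance hemodialysis (HD) session lasts about four hours.  Nine
time-varying measurements are available: staff vitals (systolic and
diastolic blood pressure, pulse pressure, pulse rate) recorded every 30–60
minutes, and machine channels (blood flow rate, venous pressure,
transmembranous pressure, ultrafiltration rate, cumulative ultrafiltration
volume) logged automatically whenever venous or transmembranous pressure
changes from the previous record — hence at irregular, data-driven times.
Four static fields (age, gender, dialysis vintage in years, predialytic
weight in kg) complete a session's record.  The outcome is binary: did the
session carry at least one adverse event (27 closed categories, from muscle
cramps to cardiac symptoms)?  For event sessions only data strictly before
the first event are usable — anything later would condition on the outcome.

## Cleaning rules

* **Session-start artifact.** The first data point of every measurement is
  dropped iff the blood flow rate differs between the first two blood-flow
  records (strict inequality of the recorded values, tolerance 0; machine
  blood-flow values are integers in practice).
* **Interruptions.** Every record whose contemporaneous blood flow rate (by
  LOCF) is ≤ 0 is dropped.  One maximal contiguous run of such record times
  counts as one interruption regardless of duration; two or more
  interruptions reject the session.  Staff vitals are exempt from the
  point-drop rule unless their timestamp falls inside an interruption run,
  because the rule targets machine data artifacts.
* **Record floor.** A surviving session must keep ≥ 3 records per
  measurement, the minimum for slope, R² and second-derivative features.
  Sessions under the floor are excluded with an explicit reason.

Cleaning is idempotent on machine-like data, where the start artifact is a
single ramp point.  An adversarial series whose blood flow strictly
increases over its first several records could trigger the first-point rule
repeatedly; such data do not arise from dialysis machines and the rule is
applied once, at ingestion.

## LOCF, truncation and cutoffs

`value_at(session, j, t)` returns the most recent recorded value of
measurement `j` at or before `t` — right-continuous, piecewise constant,
exact at record times.  Truncation rules build on it:

* **Event sessions** keep records strictly before the first (in-scope)
  event.
* **Cutoff experiments** stop collection `m ∈ {0,5,10,15,20,60}` minutes
  before the anchor (first event time, or last record time for event-free
  sessions).  `m = 0` on an event session reproduces plain truncation
  (strictly-before); for `m > 0` a record exactly at `anchor − m` is kept.
  Cutoffs nest monotonically: a larger `m` keeps a subset of the records.
* **Negative truncation** assigns event-free sessions an endpoint, fixed
  (e.g. 198 min) or uniform in a window (180–210 or 150–210 min), appending
  an LOCF endpoint record at `T_end` for every measurement so the endpoint
  is defined the same way as a value at an arbitrary time.

## The 84-feature registry

Each session maps to exactly 84 features: per-measurement linear summaries
(mean; standard deviation of the mean; coefficient of variation; OLS slope
per minute and R² of value on time; max; min), first- and second-order
finite-difference derivative summaries (max/min/mean) of venous and
transmembranous pressure, ultrafiltration-rate change statistics (count of
changes and mean signed change), and the four demographics.  Conventions:

* **"Standard deviation of the mean"** is the standard error: sample SD
  (n−1 denominator) divided by √n.  CV is sample SD over |mean|, 0 for a
  constant series; a zero mean with nonzero SD yields a flagged non-finite
  value that excludes the session for that feature (pressures and flows are
  positive in practice, so this does not occur on realistic data).
* **Regression** is unweighted OLS on the recorded `(t, y)` points only —
  no LOCF densification, which would distort variance features.  Constant
  series have slope 0 and R² defined as 0.
* **Derivatives** are consecutive finite differences,
  `d1_k = Δy/Δt`, `d2_k = Δd1/Δt`, per minute; duplicate timestamps are
  collapsed to the last value before differencing.
* **Index map.** A handful of registry indices are pinned by the analysis
  this package reproduces: the ultrafiltration block occupies indices 70–83
  (rate 70–77 with the change count at 76 and mean change at 77; volume
  78–83 with the maximum at 78 and the regression slope at 82); the
  venous-pressure derivative block sits at 47–52; the blood-pressure-related
  group has exactly 24 members (7 summaries each for systolic, diastolic
  and pulse pressure, plus the three pulse-pressure first-derivative
  summaries); the demographic group is {age, gender, vintage, weight}; and
  a 21-feature "top" group (disjoint from ultrafiltration) is tagged at
  indices {2, 5, 6, 8, 11, 14, 17, 20, 21, 26, 29, 31, 36, 47–52, 57, 59}.
  The remaining slot assignments are this package's canonical ordering —
  the original feature table is not public, so index-level fidelity beyond
  the pinned constraints is not claimed.  The registry is exportable to
  `registry.yaml` (`hdadverse registry --out registry.yaml`) and custom
  registries can be loaded back.
* Gender is encoded male→1, female→0 for modeling.

## Models

**Averaged perceptron** (primary).  Features are standardized to zero mean
and unit SD (SD floor 1e-8) on the training folds; learning rate 20 and 20
epochs are the reference settings and are only meaningful on that bounded
scale.  Per epoch, examples are visited in a seed-shuffled order; under the
±1 label convention a misclassification (`y·w·x ≤ 0`) updates
`w ← w + lr·y·x`; the model returns the average of the weight vector over
every visit, which stabilizes the final-weights perceptron.  The score is
the averaged-weight dot product (plus bias); ties at the threshold classify
as 0, favoring specificity, which matches the high-specificity operating
point this analysis runs at under ~10:1 class imbalance.  The event
"probability" is a logistic squashing `1/(1+e^{−s})` of the score (clamped
away from exact 0 under floating-point underflow); the 0.8
probability-consistency threshold is applied to this value.

**RUSBoost** (selection scorer).  AdaBoost.M1 where each round draws a
fresh uniform undersample of the majority class at a 1:1 ratio to the
minority, fits a shallow decision tree (scikit-learn) on the sample with
the current example weights, computes the round weight
`α = ½·ln((1−ε)/ε)` from the weighted error on the full set, and
re-weights.  The example-weight vector is renormalized every round.
Defaults: 100 rounds, depth-4 trees; the feature search uses a lighter
configuration (see below).

**Baselines.** Linear SVM and logistic regression (standardized pipelines)
and a random forest, wrapped to expose the same `fit` /
`decision_function` / `predict` contract.

## Evaluation

Four-fold cross-validation, three repeats by default, each repeat with a
fresh seed-derived shuffle.  The session partition stratifies folds by
label so both classes appear in every fold at the ~9.6% positive rate; the
interpatient partition assigns all of a patient's sessions to one fold.
Standardization is fit on training folds only.  AUC is the trapezoid area
over the threshold-sweep ROC, identical to the Mann–Whitney pairwise
probability with ties counted ½ (verified against a brute-force pairwise
estimator in the tests).  F1, sensitivity and specificity are reported at
the native threshold (score 0), not an ROC-optimized point.  Mean ROC
curves average TPR vertically on a fixed FPR grid.  The negative control
permutes the label multiset (exact-count permutation, not fresh Bernoulli
draws) and must yield mean AUC ≈ 0.5.

## Synthetic cohorts

The generator targets statistical structure, not physiology — no
cardiovascular or plasma-refill model is claimed.

* **Patients** (default 108, 39–40 sessions each): age ~ Normal(64, 12)
  truncated above 18 years; 56% male; vintage ~ Gamma(2, 3.85) years (mean
  7.7); weight ~ Normal(62, 12) truncated above 35 kg; per-patient
  baselines for pressures, pulse, blood-flow setting.
* **Machine channels**: latent venous/transmembranous pressure = baseline +
  session-level linear drift + Ornstein–Uhlenbeck jitter on a 1-minute
  grid; a record is emitted when either pressure has moved more than the
  trigger threshold (default 5 mmHg) since the last record, giving ~30–60
  irregularly spaced records per session, plus an end-of-session snapshot.
  The ultrafiltration program is a stepwise rate (0–4 staff adjustments);
  the cumulative volume is its exact integral, hence nondecreasing.  With
  probability 0.5 the first blood-flow record is a lower setup-ramp value,
  exercising the first-point rule.
* **Vitals** at visit times spaced Uniform(30, 60) minutes, rounded to
  integers; pulse pressure is derived as SBP − DBP.
* **Events**: a per-session logistic hazard on cohort-standardized latent
  quantities chosen in the configuration (e.g. SBP drift slope with a
  negative direction, session mean ultrafiltration rate with a positive
  one); the intercept is calibrated by bisection so the mean hazard equals
  the configured event fraction (default 0.096).  Event sessions draw a
  first-event time from a triangular law in the second half of the session
  with probability 0.8 (else in 70–120 min), because the analysis only uses
  the first event's time; event types are sampled from the documented
  27-category episode-count distribution, independent of the covariates.
* **Interruption injection** adds one or two non-overlapping zero-flow
  intervals (5–12 min) to chosen session fractions so cleaning decisions
  can be checked against known counts.
* All randomness flows from one root seed through named substreams; the
  same configuration is byte-identical on re-simulation.

What passing tests on these cohorts do **not** show: behavior under real
sensor noise and missingness patterns, type-specific event mechanisms
(synthetic event types are exchangeable), drifts that are nonlinear in
time, or transfer of the reference hyperparameters to a real cohort.  The
original study's absolute AUCs came from an unreleased clinical data set
and are treated as qualitative references only.

## Session length is a leakage channel

Truncating positive sessions at their first event makes session length
itself informative: even with a feature-independent hazard, features such
as the maximal cumulative ultrafiltration volume separate truncated
positives from full-length negatives (cross-validated AUC ≈ 0.85–0.9 on a
null cohort).  The package therefore treats length explicitly: the
null-calibration test extracts features from untruncated sessions (where
the labels are independent of the features by construction), the truncation
experiments quantify the effect, and the signal-recovery test draws
negative endpoints from the positive event-time law so that the injected
covariate — not length — must carry the discrimination.  This mirrors the
negative-session truncation analyses of the reference design.

## Greedy feature-combination search

Level 1 scores every single feature by 4-fold cross-validated RUSBoost and
keeps the top feature.  At level s+1, every retained size-s combination is
extended by each unused feature; extensions are kept iff they score
strictly above the best retained score of level s (the benchmark is per
level, not per parent).  The score is held-out sensitivity + specificity
pooled over folds (range 0–2, chance ≈ 1; imbalance-robust); a
(TP+TN)/n convention in [0, 1] is available behind a switch.  Because the
keep-all-improving rule can explode combinatorially over 84 features,
retained lists are truncated to a beam cap (default 50) by score with
deterministic tie-breaking; the cap can be disabled, in which case the
trace equals an exhaustive enumeration under the same rule (verified on
small instances).  All combinations within a level share one scoring seed
so comparisons are paired.  Key features are ranked by appearance
frequency across the deepest level's retained combinations, ties broken by
best containing-combination score, then lower index.  The search is greedy
by construction: a feature pair that is jointly informative but
individually useless (XOR) is found only through whichever singleton tops
level 1 — documented, not worked around.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything on synthetic
cohorts sized for a laptop-class single CPU: the negative-control
calibration uses the full study-scale cohort (~4 200 sessions), recovery
and experiment tests use 300–500 sessions, and the search tests use a
light scorer (8–12 boosting rounds, depth-2 trees, beam 5, combinations up
to size 8).  These sizes are the package's defaults for its own checks;
all of them are plain function arguments.  Oracle agreement for the
summary features is asserted to 1e-10 relative; serialization round-trips
exactly (floats written at shortest round-trippable precision and parsed
in round-trip mode).  Seeds derived from a root seed stay below 2³¹.

## Known limitations

* The per-index registry layout beyond the pinned constraints is a
  reconstruction; models trained here are not weight-compatible with any
  other implementation of the same analysis.
* The reference platform's averaged-perceptron internals (its exact update
  and the meaning of its learning rate) are undocumented; equivalence to
  its outputs is not claimed.
* The generator's event types carry no type-specific signal, so the
  event-group analyses (cramps, blood-pressure elevation) are exercised
  structurally rather than mechanistically.
* No imputation beyond LOCF, no outlier handling, no smoothing, no deep
  models, no hyperparameter search beyond the reference settings.
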