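# Methods

This note documents the models, conventions and design choices behind
`tapdyn`, in the order data flows through the package.

## Keystroke logs and timing semantics

A log row records one keypress: time-of-day timestamp (`hh:mm:ss.sss`), hand
class (`L`/`R`/`S`), keyboard column (1–5), hold time (ms), and — when the key
has a successor in the same typing session — the two-letter direction class
and the latency (ms) to the next key-down. Flight time is always derived as
latency − hold and may be negative (rollover). Characters are never stored;
the privacy model records only hand and column.

Sessions are implicit: an event without a recorded latency ends its session,
and any latency above a configurable session gap (default 5 minutes) is
treated the same way on read, since a timing pair spanning such a gap
reflects a break, not movement. Timestamps carry no date, so the reader
restores temporal order with a single stable sort over the file — all
sessions in one file are assumed to share one day's clock, and recordings
from different days belong in different files. Malformed rows are collected
and reported; a file with more than 10 % malformed rows is rejected outright
rather than silently truncated.

## Feature extraction

Each subject is summarised by 27 features, partitioned 9 (Hold) / 18
(Latency) as described in the README. Conventions, fixed here and used
everywhere:

* **SD** uses the n−1 denominator.
* **Skewness** is the adjusted (bias-corrected) Fisher–Pearson statistic;
  **kurtosis** is bias-corrected *excess* kurtosis (normal → 0).
* Skewness and kurtosis are reported as missing below **30** observations in
  a category, or when the sample has zero spread — both moments are unstable
  in small samples, and missingness is handled by mean imputation downstream
  rather than by propagating noisy values.
* The pause threshold is **inclusive at 800 ms**: a latency of exactly 800 ms
  is movement, anything greater is a pause.
* Asymmetry features are **signed** (left − right, LR − RL, LL − RR), so the
  direction of sidedness is preserved; mirroring all hand labels negates them
  exactly (a property the tests enforce).
* Space-involving pairs (LS/RS/SL/SR/SS) are classified and counted but enter
  no latency feature, and space-bar holds enter neither hand's hold features:
  the space key is pressed by either thumb and carries no left/right signal.
* Latency statistics are pooled globally across sessions after pause
  filtering, not computed per session and averaged; at the sample sizes the
  eligibility rule enforces the difference is negligible, and pooling keeps
  the estimators well defined for rare direction classes.

Eligibility screening keeps subjects with at least 2000 total captured
keystrokes (total, not per direction class), restricts PD subjects to mild
severity (early-detection cohort), and excludes levodopa users (the drug
suppresses the motor signal being measured). Each exclusion is reported with
its reasons.

## Ensemble classifier

Per feature group: mean imputation → min–max scaling to [0, 1] → linear
discriminant analysis down to one component (the maximum for a binary
label), then eight base classifiers fit on the projected training data. All
preprocessing state is learned inside the training set only — under
cross-validation it is refit inside every fold — so no test-set statistic
ever leaks into the model. At prediction time, missing features are filled
with the stored training means.

Base models use library defaults apart from pinned seeds and two iteration
caps (`MLPClassifier(max_iter=2000)`, `LogisticRegression(max_iter=1000)`)
that only move the optimisers' stopping points, not their objectives; the
non-default arguments are pinned in one place (`PINNED_PARAMS`) so results
are stable across library upgrades. The MLP can still hit its cap on
near-degenerate 1-D inputs; this affects convergence warnings, not
determinism.

The combination rule is implemented literally as the weighted sum shown in
the README — Hold probabilities averaged as-is, Latency probabilities
expanded about 0.5 by `Wt` — rather than rewritten as a weighted mean of
group means; the two agree except at the clamping edges. With `Wt = 1.2` the
raw value can reach 1.05 or −0.05, so it is clamped to [0, 1] afterwards and
both raw and clamped values are kept. With `Wt = 1` the rule reduces exactly
to the plain mean of all sixteen probabilities (property-tested). The
decision threshold `P_PD ≥ 0.5` is inclusive.

## Evaluation

Two modes: a stratified 0.65:0.35 hold-out split, and stratified k-fold
cross-validation (default k = 10), the latter being the headline mode since
a one-third test set of a ~50-subject cohort is small. Folds are stratified
because the PD class is the minority; k is reduced with a warning when it
exceeds the smaller class size (stratified folds need at least one member of
each class per fold, so a literal leave-one-out is not offered). Fold
metrics are averaged, and a pooled report is built from each subject's
single out-of-fold prediction.

Sensitivity, specificity and accuracy are percentages; any metric with a
zero denominator is NaN, never silently 0. Displayed values round half away
from zero to integers; full precision is kept internally. AUC is the
rank-based construction (ties count one half). Welch's heteroscedastic
one-way ANOVA (with Welch–Satterthwaite degrees of freedom) compares the
predicted probabilities of the two predicted groups; it is reported as
undefined when any group has zero variance — which genuinely happens when a
perfectly separated cohort drives all probabilities to the clamping edges.

## Synthetic cohorts

The simulator generates what the method assumes: independent hand/column
draws from a fixed English-typing frequency table (no linguistic structure —
the features depend only on marginal and directional timing distributions),
and log-normal hold/latency draws (human inter-keystroke intervals are
positive and right-skewed) moment-matched to target means and SDs. Defaults
keep hold times around 100 ± 15 ms and latencies around 190–260 ms by
direction, inside the typical 60–140 ms and 50–800 ms bands, with a 2 %
baseline pause rate (pauses drawn between 1.5 and 8 s).

Between-subject variability is essential: each subject draws a common speed
offset (SD 10 ms), per-hand offsets (SD 3 ms), per-direction offsets
(SD 8 ms) and an SD offset (SD 2.5 ms) around the population baselines.
Without it, subject-level feature means would collapse onto the group values
and any nonzero effect would be trivially separable.

PD effects, all applied on top of the subject baseline: a +25 ms mean shift
(bradykinesia), a ×2 variance inflation (which also raises log-normal
skewness and kurtosis), an optional additive exponential right tail for
extra skew (off by default), a 1.3× multiplicative slowing of one side's
hold times and of latencies of pairs *ending* on that side (unilateral
onset; controls always have factor exactly 1), and a doubled pause rate
(hesitation). The default cohort is 20 PD / 33 controls with 2000–3000
keystrokes per subject. Tremor oscillation (4–6 Hz) is deliberately not
simulated; it is a separate cardinal symptom outside this classifier's
feature set.

What passing tests therefore show: the pipeline recovers planted effects of
this kind and size near-perfectly (CV AUC 1.0) and scores at chance on null
cohorts (mean AUC ≈ 0.5 over 20 replicates, demonstrating leakage-free
evaluation). What they do not show: performance on real typing, where
effects are smaller, timing distributions are not exactly log-normal, and
keystroke sequences carry linguistic and diurnal structure the simulator
omits.

## Numerical and degenerate-input choices

* Simulated timings are rounded to 0.1 ms and timestamps to 1 ms, so written
  logs round-trip bit-exactly; floats are serialised with `repr`.
* A feature that is constant across training data min–max-scales to 0 (with
  a warning); an all-missing feature column imputes to 0 rather than being
  dropped, keeping the 27-column layout stable.
* Empty samples yield all-NaN moment statistics, never exceptions; an
  ineligible log yields an explicit result object with reasons, never an
  exception.
* Every stochastic component (simulator, fold shuffling, stochastic base
  models) takes an explicit seed; identical seeds give byte-identical
  cohorts and identical prediction tables.

## Problem sizes used in validation

The validation suite runs the full pipeline at the default cohort scale
(53 subjects × 2000–3000 keystrokes) for the strong-effect recovery check
and across 20 replicate null cohorts for calibration; unit-level checks use
smaller cohorts (8–18 subjects, 400–500 keystrokes with a relaxed
eligibility minimum) where the property under test does not depend on
cohort size.
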