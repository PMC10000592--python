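# Methods

## Record model and inclusion rules

A CTG record is a pair of equal-length series — fetal heart rate
(bpm) and uterine contraction pressure (arbitrary units) — at a
common sample rate (default 4 Hz, the conventional CTG rate), with a
per-sample boolean validity mask and clinical metadata. The mask
covers both signal loss and gross noise; the two are deliberately not
distinguished, since every downstream operator treats them
identically (excluded from estimation, events may not bridge a masked
run longer than 15 s). Spans are 0-based half-open sample intervals.

Cohort inclusion applies, per record: a minimum stage-1 duration
conditioned on umbilical pH (pH ≤ 7.15 requires ≥ 30 min, pH > 7.15
requires ≥ 40 min, thresholds inclusive), end-of-signal-to-birth
< 30 min, stage-1 missing signal ≤ 50% (inclusive), gestation
> 36 weeks, maternal age ≥ 18. Durations are wall-clock, not
mask-valid, minutes — the alternative reading was possible but the
wall-clock one is simpler and stated in the docstring. Stage-1
analysis is truncated to the final 60 min (the hour adjacent to
stage 2). A missing pH raises rather than silently including or
excluding. The selection function is pure: identical inputs give
identical decisions and the full list of violated rules.

## Baseline

Estimated independently in 10-min windows advancing by 7 min (3-min
overlap); a trailing partial window is clamped to the record end.
Each window starts from a *virtual baseline* — the densest 1-bpm
histogram bin of the valid samples, a mode-like statistic robust to
records whose decelerations occupy close to half the window — then
iterates: keep samples within ±10 bpm of the current estimate (the
event envelope; accelerations and decelerations fall outside it),
re-average, stop when the update falls below 0.5 bpm or after 20
iterations. The window value is accepted only if the samples near the
final estimate total more than 120 s (not necessarily contiguous) and
the value lies in [50, 220] bpm; otherwise the window is
*unidentifiable* — a value, not an exception, so wholly masked
windows degrade gracefully.

For per-sample use the window values are linearly interpolated
between window centres (constant beyond the outermost centres).
Interpolation, rather than a stepwise series, tracks slow baseline
drift: with windows every 7 min the residual against a ±3 bpm,
25-min-period drift stays near 1 bpm, which matters because excursion
detection keys on baseline crossings.

Baseline bands: Bradycardia < 110 bpm, Normal 110–160, Tachycardia
> 160 (standard guideline cut-offs).

## Variability

Within each discrete 10-min slice, each 1-min segment contributes the
standard deviation of (FHR − baseline) over its valid, event-free
samples, provided the oscillation completes more than one cycle
(cycles = baseline crossings / 2). A slice combines its qualifying
segments by **mean** (default) or **sum** (`slice_mode="sum"`); the
record value is the mean over slices. The sum convention inflates the
value by roughly the number of qualifying segments per slice and is
incompatible with the bpm-scale amplitude bands used to categorise
variability (Absent ≈ 0, Minimal ≤ 5, Moderate 6–25, Marked > 25), so
the mean is the default; both are implemented and tested (a pure
sinusoid of amplitude *a* gives per-segment SD *a*/√2, and sum mode
returns exactly 10× the mean mode on a fully qualifying slice). No
qualifying segment anywhere ⇒ variability Undetermined, an explicit
category end to end.

## Events

Excursion machinery shared by both detectors: the trace is smoothed
by a 9-s moving average (masked samples interpolated first), the
signed deviation from the interpolated baseline is thresholded at
zero, and maximal runs are split wherever a masked run exceeds 15 s.
The 9-s window divides smoothed noise SD by ~6, so moderate
variability no longer fragments genuine events, while a raised-cosine
event of ≥ 30 s loses only a few percent of its peak.

* **Accelerations** (crisp): positive excursions kept when 15 s ≤
  duration ≤ 10 min and peak − baseline > 15 bpm; qualifying
  excursions longer than 10 min are flagged baseline changes, not
  events.
* **Decelerations** (fuzzy): negative excursions scored
  min(μ_duration, μ_depth) with trapezoidal memberships — μ_duration
  0 below 10 s, linear to 1 at 15 s, 1 up to 10 min, 0 beyond;
  μ_depth 0 below 10 bpm, linear to 1 at 15 bpm — emitted at
  membership ≥ 0.5 by default. Unambiguous events (≥ 15 s, ≥ 15 bpm)
  score exactly 1, so on such events the fuzzy detector provably
  equals a crisp detector (tested via a mirror-image oracle: the
  acceleration detector applied to the negated deviation). Membership
  is monotone in depth and, below 10 min, in duration
  (property-tested).
* **Contractions**: `scipy.signal.find_peaks` on the UCP channel,
  prominence ≥ 15 units, ≥ 45 s apart; onsets/offsets at 90%
  prominence drop.
* **Typing**: onset-to-nadir < 30 s ⇒ variable (abrupt, the standard
  convention); otherwise gradual — nadir within ±15 s of the nearest
  contraction peak ⇒ early, lagging by > 15 s ⇒ late; no contraction
  within ±120 s, or a nadir *leading* the peak by > 15 s ⇒ variable
  (uncoupled). An empty contraction log types gradual decelerations
  variable with a warning. The trapezoidal memberships and the 30-s
  rule are configurable; they stand on their own as the canonical
  crisp/fuzzy reading of the guideline definitions.

* **Sinusoidal pattern**: requires ≥ 20 min of valid signal
  (else Undetermined); Present when the Welch spectrum of
  (FHR − baseline) concentrates ≥ 50% of its power in 2–5 cycles/min,
  the equivalent sine amplitude √(2·band variance) lies in 5–15 bpm,
  and no accelerations were detected; Absent otherwise (a near-flat
  trace short-circuits to Absent).

The 11-feature vector: baseline (bpm), baseline type, variability
(bpm), variability type, acceleration presence, acceleration count,
early/late/variable deceleration counts, sinusoidal-pattern category,
stage of labor. Undetermined propagates as its own category; the
numeric encoder carries it as value 0 plus an explicit
determined/undetermined indicator column rather than imputing.

## Classification harness

Six simulated or real annotations per record reduce to a final label
by majority vote; ties break toward the more severe class — in the
clinical gray zone the cautious reading is the defensible default.
The tie rule is exercised exhaustively against a brute-force oracle
over all 3⁶ label patterns.

SMOTE (implemented in-package) oversamples each minority class to
parity: every synthetic row interpolates, at a uniform random point,
between a minority sample and one of its k = 5 nearest minority
neighbours; k is reduced with a warning when the class is smaller
than k + 1. Synthetic rows are flagged by provenance and only ever
created inside a training fold — the harness asserts, per fold, that
no test row has SMOTE provenance. SMOTE defaults to off; it is an
opt-in augmentation.

Cross-validation is stratified 5-fold (stratification guarantees
every class in every fold; per-fold class proportions stay within one
sample of the global ones). Per fold: optional SMOTE on the training
portion, fit, predict the held-out fold, score the 9-metric set
(accuracy, weighted TPR/precision/recall/F-measure, weighted
one-vs-rest FPR, weighted one-vs-rest AUC, Cohen's kappa, RMSE on
the class integers). Folds and model initialisation are fixed by the
seed; two runs with the same seed produce identical pooled
predictions. The four classifiers are standard scikit-learn models
behind one config block — MLP with three sigmoid hidden layers
(32, 32, 32), random forest (200 trees), RBF SVM (C = 10, Platt
probabilities), bagging (50 estimators) — each preceded by
standardisation. The per-fold model-by-model Pearson correlation of
the metric vectors is available for harness-robustness checks;
zero-variance vectors yield NaN, reported as such.

## Evaluation battery

All confusion-matrix statistics take the 3×3 actual-vs-predicted
table. Sensitivity/specificity/precision are one-vs-rest,
support-weighted by default (macro available); under weighted
averaging sensitivity equals accuracy, which the tests assert.
Combined measures use the standard formulas (G-mean, DP, balanced
accuracy from macro rates, Gorodkin's multiclass MCC, Cohen's kappa,
Youden's J); DP is reported infinite when a rate touches 0 or 1,
never clipped. Chi-squared is the plain Pearson statistic without
continuity correction, df = 4, with the critical value from the
chi-squared quantile; it is verified against both a brute-force
double loop and `scipy.stats.chi2_contingency`.

Bland–Altman uses d = actual − predicted (this orientation matches
the signs of the reproduced reference values), population SD by
default (`sd_ddof=1` available), limits d̄ ± 1.96·s_d, large-sample
CIs (se(d̄) = s_d/√n, se(LoA) = s_d·√(3/n)), and an OLS regression of
d on the pairwise means as the proportional-bias check. Computed from
label sequences, the result is invariant to row order, so any
sequence realizing a given contingency table gives identical
bias/LoA (tested).

KMO is computed from the inverse correlation matrix (anti-image
partial correlations); Bartlett's sphericity is
−(n−1−(2p+5)/6)·ln det R with df = p(p−1)/2. Singular correlation
matrices (duplicated or constant columns) fail explicitly. Scree
eigenvalues come from the correlation matrix and sum to p. Multiclass
AUC is one-vs-rest with midpoint tie handling; a class absent from
the truth is NaN and excluded from the macro mean.

## Synthetic generator

The generator is the study-conditions stand-in for a clinical cohort:
each record is baseline (default 140 bpm) + slow sinusoidal drift
(default ±3 bpm, 25-min period) + band-limited Gaussian variability
(0.04–1 Hz, scaled to the target SD) + event deflections, clipped to
[50, 220] bpm; the UCP channel is a 10-unit tonus + raised-cosine
contraction bumps (~70 s, ~45 units) at the configured period with 5%
jitter. Accelerations are raised-cosine bumps (30–90 s, 18–25 bpm)
placed without overlap; decelerations attach to successive
contractions — early: raised cosine centred on the contraction peak;
late: the same shape with the nadir lagging the peak by `late_lag_s`
(default 40 s); variable: an abrupt piecewise-linear V with a 12-s
onset. The optional sinusoidal pattern is a 3.5-cycles/min, 10-bpm
sine. Gaps are contiguous masked runs (15–120 s) placed to hit the
configured fraction (≤ 0.5). Ground truth records every event's exact
start/extremum/end, the true baseline series, the true variability
SD, the class label, and six simulated rater labels. Identical
configs are bit-identical.

Cohort recipes (the defaults define the test conditions): Normal —
baseline 120–150 bpm, variability 6–10 bpm, 3–5 accelerations, at
most one benign early deceleration; Suspicious — one of reduced
variability (2.5–4.5 bpm), mild tachy/bradycardia, or 2–3 variable
decelerations; Pathological — variability 0.5–2 bpm with recurrent
late decelerations (one per contraction, minus at most one), or a
sinusoidal variant (20%). Default class mix 0.34/0.39/0.27, matching
a realistic annotated intrapartum case mix. Stage-2 records shorten
the contraction period (80–110 s vs 130–240 s) and deepen the
recurrent decelerations. Gradual decelerations are generated at
durations ≥ 80 s in stage 1 so their onset-to-nadir stays clearly
gradual under the 30-s rule; stage-2 periods cannot host such long
events, so stage-2 typing is intentionally harder — typing accuracy
is asserted on stage-1 cohorts.

Raters err only into adjacent classes (1↔2, 2↔3), reflecting the
clinical gray zone; with 0.8 per-rater concordance and uniform truth,
exact enumeration over the 6-rater outcomes puts majority-vote
recovery at 0.952 under the severity tie-break.

**What the generator does not emulate** — and hence what passing
tests do not show about clinical data: the true (uncharacterised)
noise spectrum of clinical FHR (the band-limited Gaussian is a
stand-in), maternal-heart-rate artifacts, transducer drift and
re-positioning transients, overlapping or compound decelerations,
and genuinely ambiguous borderline morphologies. Detection F1 ≈ 0.97
and cross-validated accuracy ≈ 0.99 on this cohort demonstrate the
pipeline's internal consistency against known truth, not clinical
performance.

## Numerical choices and problem sizes

Convergence and thresholds as above (baseline tolerance 0.5 bpm, max
20 iterations; fuzzy emission threshold 0.5; contraction prominence
15). Display rounding is half-away-from-zero to 3 decimals. The test
and acceptance runs use a 300-record, 30-min, 4-Hz stage-1 cohort
with 0.9-concordant raters — large enough for stable detection/
classification statistics while keeping a full run in tens of
seconds. Event-to-truth matching uses greedy interval assignment at
IoU ≥ 0.3.

## Known limitations

No frequency-domain HRV indices, pH prediction, or artifact removal;
deceleration typing is rule-based (abruptness + timing), not a
trained morphology classifier; the WFDB reader is a thin optional
shim; stage-2 feature interpretation is extracted identically to
stage 1 with only the stage label distinguishing them downstream.
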