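# Methods

## Problem and model

`telestress` predicts whether an employee will be stress-positive next week
from this week's passively collected data. Stress is measured by the Kessler
K6 questionnaire (six items scored 0–4, total 0–24); a total of 5 or more is
positive (severity classes: 1 = 0–4, 2 = 5–8, 3 = 9–12, 4 = ≥ 13). The
predictors are ~50 weekly aggregates of three daily streams — wearable
(sleep, activity, heart rate), work shifts (actual vs scheduled times,
working from home, absence), and weekly questionnaire behavior (outings,
lunches skipped) — always lagged one week: the feature vector of week *t−1*
predicts the label of week *t*, so a 12-week record yields at most 11
supervised instances.

The core idea is *training-data personalization by working style*. Each
participant's teleworking rate is the fraction of worked days spent working
from home. For each prediction target, the 20 participants with the nearest
teleworking rates form a neighborhood cluster whose data train that target's
individual model (ties at the cluster boundary are resolved by seeded uniform
sampling). Three training regimes are compared:

| method | training data | threshold |
|---|---|---|
| `single` | everyone's label weeks 2–7 | 0.5 |
| `proposed1` | cluster's all 11 weeks + target's weeks 2–7 | 0.5 |
| `proposed2` | cluster's weeks 2–7 + target's weeks 2–7 | adapted on cluster's weeks 8–12 |

Test data are always the target's label weeks 8–12. "First 7 weeks" and
"last 5 weeks" are calendar label weeks: because instances carry a one-week
lag, the train period holds label weeks 2–7 (6 instances) and the test period
label weeks 8–12 (5 instances). This is the only split of 11 lagged
instances consistent with a 7/5 calendar split and no overlap.

The learner is XGBoost (binary logistic) with `max_depth=6`,
`learning_rate=0.3`, `n_estimators=100`; no hyperparameter search. Missing
feature values are left to XGBoost's native missing-branch handling — no
imputation anywhere. A score ≥ threshold predicts positive (an explicit
boundary convention).

### Threshold adaptation (`proposed2`)

On the cluster's held-out last five weeks, the decision threshold is chosen
to make the true-positive rate exceed 0.8 with the smallest attainable
false-positive rate. Candidate thresholds are the distinct observed scores
plus one value above the maximum; predictions only change at observed scores,
so this scan is exact. Ties on FP rate break toward the higher threshold. If
no candidate satisfies TP > 0.8 (impossible when at least one positive is
present, since the minimal score predicts everything positive, but guarded
anyway), the TP-maximizing threshold is returned flagged
`constraint_met=False`. The constraint is enforced on the adaptation set
only; nothing guarantees TP > 0.8 on test data.

### Evaluation

Predictions are pooled over all targets and weeks (micro evaluation) into
one confusion matrix, TP rate = TP/(TP+FN), FP rate = FP/(FP+TN), and AUROC
by the rank (Mann–Whitney) formulation with ties counted ½. Per-target
macro diagnostics are emitted alongside (`evaluation_per_target.csv`).

### Interpretation

Per individual model, features are ranked by gain importance (total
objective reduction from splits on the feature; deterministic name
tie-break; top-10 padded with zero-gain names in stable order). Exact
TreeSHAP values are computed on the model's test-week instances via
XGBoost's `pred_contribs` predictor, so each row's values sum to the model
margin (asserted to 1e-4). The contribution direction of a feature is
cov(x, φ)/sd(x) with unbiased (n−1) estimators; rows with a missing feature
value are dropped, and a zero-variance feature is reported undefined.
Models are stratified by their target's teleworking level — low (< 0.2),
middle (0.2 to < 0.6), high (≥ 0.6) — and per level the pipeline tabulates
top-10 category counts (sleep / activity / work / questionnaire; a flag
merges questionnaire into work for a strict three-category view) and the
per-feature distribution of direction statistics. The per-level feature
table is ordered by mean within-model rank (rank 1 = best), a scale-free
average across models.

## Feature registry

The default registry has exactly 50 entries: weekly mean and unbiased SD of
15 daily variables (sleep duration/efficiency/start/end; steps, distance,
floors, calories; daily heart-rate mean and SD; working hours, work
start/end, working-hour gap = actual − scheduled hours, scheduled hours);
six weekly counts (worked days, WFH days, absence days, within-week
teleworking rate, outings, lunches skipped); four weekly sums (steps,
distance, floors, calories); five absolute deviations of a weekly mean from
the participant's study-long baseline (heart rate, calories, sleep duration,
work start, steps); and five week-over-week deltas (sleep duration mean,
steps sum, heart-rate mean, working-hours mean, and the previous K6 total).
The K6 delta uses earlier questionnaire answers as a predictor; it is
legitimate under the one-week lag but can be excluded
(`include_prior_k6=False`, leaving 49 features) by users who consider it too
close to the label. The registry is replaceable wholesale from YAML.

Weekly aggregation follows two rules: a mean is omitted only when the
variable is missing for all 7 days; the unbiased SD is omitted when fewer
than 2 daily values are present. Weeks run Monday–Sunday; participants work
Monday–Friday, and work-derived features use worked (non-absent) days only.
Clock times are minutes from midnight, signed, so a 23:30 sleep onset is
−30 and no midnight wrap occurs.

## Synthetic cohort generator

No raw cohort of this kind is publicly deposited, so the package ships a
generator that emulates all three streams and *plants* a known stress
process, making every downstream stage testable against ground truth.

**Streams.** Per-participant baselines are drawn once (sleep ≈ N(420, 35²)
min, efficiency ≈ 93%, sleep onset ≈ 23:20, steps lognormal with median
≈ 7500, heart rate ≈ N(70, 6²) bpm with daily SD ≈ 9, calories ≈ 2100 kcal
correlated with steps, scheduled work 9:00–17:30 with 8 scheduled hours,
habitual clock-in offset and over/under-time); daily values add day-level
noise. These magnitudes are ordinary for office workers wearing a wrist
device; all are internal to the generator and the planted process is
standardized, so conclusions do not hinge on them. Teleworking rates are
drawn from a three-component uniform mixture over the level intervals
[0, 0.2), [0.2, 0.6), [0.6, 0.79] with weights 0.432/0.363/0.205 (the level
shares of the motivating study population; 0.79 is its maximum observed
rate). WFH days are assigned so each participant's realized rate matches the
assigned one to within rounding (≤ 0.5 per worked day). Absences occur with
probability 0.02/workday; wearable device-days drop out with probability
0.05 (per-stream probabilities configurable), exercising the missingness
rules.

**Labels.** The week-*t* latent logit is
`c + u_i + Σ_k β_k g_k(x_{i,t−1}) + ε_{i,t}` with participant random
intercept `u_i ~ N(0, 0.5²)` and noise `ε ~ N(0, noise_scale²)`,
`noise_scale` default 1.0. Each planted effect names a registry feature, a
teleworking-level scope (low/middle/high/all), a shape — `linear`
(cohort-standardized value), `absolute_deviation` (|x − participant mean|,
standardized), `u_shaped` ((x − participant mean)², standardized) — and a
signed logit coefficient. Week-1 labels have no lagged features and carry
only intercepts and noise. The global intercept `c` is solved by Brent root
finding so the marginal positive prevalence equals
`positive_prevalence_target` (default 0.3; the study never states its K6
positive rate, so this stays configurable). The K6 total is then drawn
consistently with the binary label (0–4 uniform if negative; 5 + Poisson(3)
truncated at 24 if positive) and split over six items capped at 4.

The default effect table plants level-specific signals with distinct
directions per level: for high teleworking, lunches skipped (+2.0),
heart-rate variability (+1.5), sleep duration (−1.5); for low/middle,
working hours (+1.5); for low, heart-rate variability (−1.5) and
absolute deviation of work start time (+1.5); for everyone, step volume
(−1.0). Effects may not reference the prior-K6 delta (circular).

**What the generator does not emulate.** Circadian structure, per-minute
heart rate, weekday/weekend activity asymmetry, autocorrelated or
informative missingness, panel attrition, and any real covariance between
behavior and questionnaire answering. Passing tests therefore show that the
pipeline recovers the signals it is pointed at under controlled conditions —
not that comparable accuracy would be reached on real cohort data.

## Numerical and design choices

- **Determinism.** Cohorts are pure functions of the spec (seed included).
  Experiments derive one seed per target from the experiment seed and a CRC32
  of the target id, so runs are reproducible while targets stay independent.
- **Single-class training sets** raise a named error; the experiment runner
  skips that target and logs it. A `proposed2` target whose adaptation set
  has no positives keeps the fixed 0.5 threshold with a warning.
- **Teleworking rates** are computed on all 12 weeks by default (one rate per
  participant); this implies a mild look-ahead for `proposed2`'s clustering,
  and a `rate_weeks` option restricts rates to the first k weeks instead.
- **Degenerate inputs.** Pools smaller than the cluster size are taken whole
  with a warning; a participant with no worked days has an undefined rate
  and is excluded from clustering; one-class test sets yield an undefined
  (NaN) AUROC while rates are still reported.
- **Problem sizes.** The simulation studies in the test suite and the
  acceptance script use 20 seeded cohorts of 60 participants × 12 weeks —
  large enough that each target has a full 20-member cluster and every
  teleworking level is populated, while keeping a full three-method
  replication fast on one core.

## Known limitations

The neighborhood metric is the scalar teleworking rate, as designed; richer
working-style distances are out of scope. SHAP quantifies what the model
uses, not causal effect of behavior on stress. The generator's planted
process is logistic and additive on the logit scale; real stress dynamics
(carry-over, trends, measurement reactivity) are not modeled.
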