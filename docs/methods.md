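# Methods

This note documents the models, conventions, and numerical choices behind
`emaaccel`, and what the simulation-based tests do and do not establish.

## Measurement model

**Epoch reintegration.** Counts-per-minute (cpm) is the sum of the four
15-s epochs aligned to each clock minute — standard ActiGraph
reintegration. Minutes with fewer than four epochs are accepted only at
the edges of a calendar day (device switched on mid-minute); a partial
minute in the interior is treated as data corruption and raises.

**Intensity classification.** The Evenson child cutpoints partition the
nonnegative integers totally and deterministically: ST ≤ 100 cpm,
LPA 101–2295 cpm, MVPA ≥ 2296 cpm, boundaries inclusive as published.

**Nonwear.** A maximal run of zero-count minutes strictly longer than 60
minutes is off-body; a 60-minute run is wear. The rule is applied to
minute-level zeros with no spike tolerance (no Choi/Troiano allowance),
because the simple run-length rule is the stated protocol for this class
of study. Runs are evaluated within calendar days: a run spanning
midnight is split at the boundary before the length test, since days are
the analysis and validity unit. Consequences: flagging is idempotent, and
splitting a series at any worn minute and re-flagging the halves gives
the same answer.

**Validity.** Day: ≥ 4 worn hours ("waking hours" is operationalized as
worn time — no sleep diary exists in this design; a documented proxy).
Participant: ≥ 4 valid days including ≥ 3 weekdays and ≥ 1 weekend day
(Saturday/Sunday by calendar). The strict 8-hour day criterion is a
configuration switch used for sensitivity analysis; eligibility under 8 h
is always a subset of eligibility under 4 h.

## Temporal matching

Surveys are matched to the accelerometer record *preceding* them on the
same day, at hour resolution (the survey platform summarizes wear to the
hour). For a survey completed at clock time *t*, the window ends at
floor-to-hour(*t*) — data through hh:59 of the prior hour. Window starts:

- first completed survey of a day: the day's first worn hour (a proxy for
  "since you woke up this morning"; configurable, and the main open
  convention in this design — wake time and midnight are the
  alternatives, not distinguishable from the data);
- subsequent surveys: floor-to-hour(previous completed survey) + 1 h.

This start convention makes consecutive windows disjoint at hour
resolution, so no accelerometer minute is double-counted across a day's
observations. Missed or expired surveys produce no observation; the
*completed* predecessor (not the prompt) anchors the next window. Windows
never span back into the previous calendar day. Empty windows (same-hour
completions) and windows with zero worn minutes are dropped.

**Standardization.** Outcomes are 60 × class minutes / worn minutes, so
each observation lies on a common 0–60 scale and the three outcomes sum
to exactly 60. The exposure is the same survey's yes/no response
(same-survey pairing: report about the window, measured before the
report).

## Estimation and inference

With Gaussian family, identity link, and independence working
correlation, the estimating equations coincide with the least-squares
normal equations; the implementation solves them directly and computes
the Huber/White cluster-robust covariance with **dyads as clusters**
(repeated surveys of one parent-child pair share unmodelled error;
participant-days would understate the correlation). The sandwich is the
uncorrected HC0-type cluster sum by default; a CR1-style factor
G/(G−1)·(N−1)/(N−p) is available via `dof_correction=True`. 95% CIs use
the normal quantile 1.96. Reference levels are chosen so the printed
contrasts are the non-reference strata: weekday, girl, school year,
white, normal weight, lowest income bracket (all configurable). Age
enters in years as a continuous covariate; income as a two-level factor
(the design exposes both codings). Interaction P values are reported
unadjusted for multiplicity, matching the reporting style of this
literature. Rank-deficient designs raise with the collinear columns
named rather than silently dropping terms — at small n whole covariate
levels can vanish from the eligible subsample, and the analyst should
decide what to do.

Wald compliance/wear comparisons ("does compliance differ by weekend,
sex, season?") reuse the same adjusted covariate set as the outcome
models, since no separate specification exists for them.

## Synthetic-data generator

The generator *defines the study conditions* for all tests:

- **Cohort** (n = 140 dyads, 8 days): covariates drawn from the observed
  sample proportions — 66/140 girls; six racial/ethnic groups of 21–25;
  67/140 overweight; 70% income < $35k; child age ~ N(6.4, 0.8²). Start
  dates are real calendar dates consistent with each dyad's season
  (summer = June–August), so weekday/weekend structure is genuine.
- **Activity** : waking span 7:00–22:00 (the EMA prompt envelope);
  minute-level first-order Markov chain over sedentary/light/MVPA with a
  stationary distribution of roughly 53/39/8%; emissions uniform within
  each state's cpm band, split multinomially across the minute's four
  epochs so reintegration is exact; off-body episodes ~ Poisson(2/day)
  with uniform 90–240-minute durations (always detectable under the
  >60-min rule). Resulting wear averages ≈ 10 h/day — a compliant
  cohort; the generator does not model gradual evening wear drop-off.
- **EMA**: four prompts/day, uniform inside the four windows;
  per-prompt Bernoulli completion at 0.83 (echoing observed compliance);
  response delay uniform within the 60-minute expiry.
- **Reporting**: the parent's yes/no is a noisy channel on the
  pre-period truth (activity item: ≥ 10 min of light+MVPA in the window;
  screen-proxy item: ≥ 30 min of sedentary truth), with default
  sensitivity 0.85 / specificity 0.80 and optional additive log-odds
  accuracy shifts by weekend, sex, season. What parents actually count
  as "physically active" is unknown; the threshold is a modeling choice
  exposed in configuration, not a fixed constant.

**What the generator does not emulate:** tri-axial raw accelerations,
device firmware artifacts, sleep-diary information, spiky nonwear,
diurnal activity trends within the waking span, parent psychology beyond
sensitivity/specificity, and informative missingness of surveys. Tests
passing on these data therefore validate the *pipeline arithmetic and
estimator calibration*, not the behavioral realism of any particular
cohort.

**Determinism.** One master seed; every participant × purpose
(cohort/activity/schedule/report) gets an independent substream via
`default_rng([seed, participant, tag])`. Identical configurations
reproduce byte-identical artifacts.

## Calibration studies

Estimator calibration uses **semi-synthetic outcomes**: the structural
pipeline produces a realistic design (exposure, modifier, covariates,
cluster sizes), which is held fixed while outcomes are redrawn as
y = Xβ\* + cluster effect + noise. The noise scale was set a priori from
the precision this literature reports: cluster SD 3 and residual SD 10
min/hr, which put the robust SE of a weekend-stratum contrast near 0.9
at ~3100 observations / 140 clusters.

- **Parameter recovery** (140 dyads × 8 days, 200 replicates): true
  effects ST −4, LPA +3, MVPA +1 min/hr with a weekend×report
  modification of −2 on ST; the estimator is exactly unbiased, and mean
  estimates land within 2 Monte Carlo SEs of truth.
- **Power** (same design): a weekend×report modification of −3 min/hr —
  the magnitude consistent with a strongly significant weekend contrast
  at the observed precision — is detected in ≈ 80% of replicates; the
  test asserts power ≥ 0.80 up to 2 binomial MC SEs.
- **Type-I error / null uniformity** (40 dyads × 4 days, 1000
  replicates): under a zero product coefficient, interaction Wald P
  values are approximately uniform (Kolmogorov–Smirnov at the 1% level).
  The reduced-scale harness fits the sparser covariate set
  (weekend, sex, age) — the full factor battery is rank-deficient on so
  small a sample — and skips the participant wear-validity screen, which
  at 4 observation days would cut 40 clusters to ~9 and confound the
  calibration question with the screening rule. **Known limitation:**
  the uncorrected cluster sandwich is anti-conservative at 40 clusters;
  its true size here is ≈ 0.073 (measured over 8000 replicates), just
  above the nominal 3–7% band, and ≈ 0.068 with the CR1 correction.
  The package deliberately keeps the uncorrected estimator as the
  default (matching the reporting convention it reproduces) and exposes
  the correction for small-cluster applications.

Problem sizes for these studies (140×8 structural base, 40×4 reduced
base, 200–1000 outcome replicates) were chosen as the smallest designs
that make the Monte Carlo error negligible relative to the tolerances.

## Reporting conventions

Percentages use decimal half-up rounding (82.8% = 3127/3776); Table-1
style shares are integer percents of the worn hour; journal-style P
rendering (".02", ".005", "<.001" below 0.001, third decimal kept near
the .05 boundary) is reproduced exactly in text outputs while raw values
are always retained in JSON.

## Known limitations

- Hour-resolution windows discard sub-hour timing (a survey at 10:01 and
  at 10:59 carry the same window); minute-resolution matching is out of
  scope by design.
- The first-window start ("first worn hour") is a proxy for wake time.
- The generator's association between parent report and measured
  activity is emergent (report = noisy function of truth), so structural
  runs do not have a "true" regression coefficient; calibration claims
  use the semi-synthetic route above.
- No bout detection, sleep scoring, or alternative nonwear algorithms.
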