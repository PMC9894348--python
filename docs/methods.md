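# Methods

## Scope and model

`casefinder` operationalizes a case-finding algorithm for NAFLD with
advanced fibrosis (METAVIR F3–4) in a primary-care diabetes population.
It is an analysis pipeline, not a disease model: every stage is a
deterministic rule over EMR tables except the logistic risk-factor models
and the synthetic-data generator.  The package is organized
statsmodels-style — `CaseFindingModel` holds the data and configuration,
`fit()` returns a `CaseFindingResults` object carrying all intermediate
tables and a `summary()` — with the underlying rules exposed as plain
functions in `emr_model`, `cohort`, `scores`, `steatosis_text`,
`cascade_metrics`, `stats_assoc` and `synthetic_data`.

## Cohort assembly

Eligibility is adult (≥ 18 at the anchor date, completed-years
convention applied uniformly everywhere ages are needed), actively
engaged (≥ 1 in-person visit or patient-initiated message inside the
engagement window, endpoints inclusive; default 2017-07-01..2020-06-30),
and diabetic by any of three arms: an active problem-list diabetes code,
HbA1c ≥ 6.5% within the two years before the anchor date (the lookback is
anchored to cohort assembly, not to each calendar year), or an active
antidiabetic medication.  Codes for gestational, steroid-induced or
pre-diabetes never satisfy the problem-list arm.

Exclusions are evidence-based over the entire record with no time
restriction: detectable HBsAg, any prior detectable HCV RNA (a later
undetectable result does not readmit the patient), or an
alcohol-use-disorder code.  Diagnosis codes are deliberately not used for
HBV/HCV.  For single-reason attrition reporting the precedence is
HBV > HCV > AUD; all evidence is retained internally.  Code sets default
to broad prefixes (E10/E11/250 diabetes; O24/R73/E09/648.8/249 excluded
diabetes types; F10/303/305.0 AUD) and are configurable because real
deployments substitute curated lists.

## Annual scores and risk groups

One FIB-4 and one NFS per patient per calendar year 2015–2020, each from
the last outpatient measurement of each component within that year,
components independent so they may come from different dates.
Same-date duplicates break toward the larger value — conservative toward
detection — and the tie rule is documented and centralized.  A year
missing any FIB-4 component (AST, ALT > 0, platelets > 0) has no FIB-4;
NFS additionally requires albumin and a BMI observation that year.
Components are never imputed or combined across calendar years; patients
with no complete year are "unscorable" and excluded from risk
categorization (not from the cohort).

The per-patient maxima of FIB-4 and NFS (independently, possibly from
different years) are categorized with age-based cutoffs evaluated at the
age on Dec 31 of the year supplying that maximum — each annual panel is
anchored to its own calendar year.  Defaults: FIB-4 low < 1.3 (< 65) /
< 2.0 (65+), high ≥ 2.67; NFS low < −1.455 / < 0.12, high > 0.676; the
age pivot and every threshold are configurable because published
age-adjusted cutoffs vary at the margins.

Discordance resolution is the package's default rule and is pluggable:
missing NFS defers to the FIB-4 category; concordance passes through; a
high NFS bumps a non-high FIB-4 category up exactly one level; any other
discordance defers to FIB-4.  Applied cell-wise to the reference
cross-tabulation of 2206 scored patients this rule reproduces the
reported low-risk total exactly (1018) and the other two groups to within
one patient (578/610 vs 577/611).  The one-patient discrepancy cannot be
resolved from printed data and is deliberately left standing; forcing
agreement would require an ad hoc exception with no evidential basis.

## Steatosis text review

A case-insensitive substring matcher over {"fatty liver", "steatosis"}
on ultrasound report text, any report from 2000 onward, ultrasound
modality only.  Negation handling (cue within five tokens before the
match; whitespace tokenization with punctuation stripped) is implemented
but OFF by default: the plain matcher is the documented method, and
enabling negation changes a detector that is exactly characterizable
(equivalent to a regex search) into one that is merely plausible.

## Target group, cascade, outcomes, performance

The intervention target is high-risk ∧ age < 75 at the anchor (strict
inequality; the limit is configurable) ∧ alive ∧ in-system, with removals
tallied age-first.  Cascade events per patient must form a prefix of
messaged → referred → triage_accepted → scheduled → visit_completed →
nafld_diagnosed → staging_completed → advanced_fibrosis; the ledger
reports per-stage counts and whole-percent yields against the preceding
stage.  Fibrosis outcomes: F3–4 iff elastography LSM strictly above
8 kPa, MRE/biopsy stage ∈ {3, 4}, definitive radiological cirrhosis, or a
direct clinical F3–4 assessment (accepted as-is for
modality="clinical").  Performance tables count staged patients only;
metrics are percentages rounded half-up to one decimal; a zero
denominator reports as undefined rather than zero.

## Risk-factor models

Covariates use the study cutpoints (HbA1c ≥ 8%, HDL < 40,
triglycerides ≥ 150, platelets < 150, BMI classes with Asian-specific
cutpoints 18.5/23/27 vs 18.5/25/30) from the most recent qualifying
outpatient lab at or before the anchor.  FIB-4 enters continuously; the
per-patient value is the maximum across years (the same quantity used for
categorization), with `median` and `last` available behind a policy
switch since summary language in reports is sometimes ambiguous on this
point.  NFS is excluded from all models because of its collinearity with
FIB-4.  Bivariable models fit each predictor alone; the multivariable
model fits sex, race/ethnicity, BMI class, glycemic control and FIB-4.
Fitting is maximum-likelihood logistic regression via statsmodels; odds
ratios carry Wald 95% CIs on the log-odds scale (the standard default,
consistent with the wide intervals typical at these sample sizes).
Complete-case analysis with logged drop counts; a categorical level with
no observations in the analysis sample is reported "not estimable" and
its all-zero column dropped so the remaining fit stays well-posed;
separation/non-convergence is flagged on the result, never silent.  A
variance-inflation report is provided as an advisory collinearity screen
only.

## Synthetic-data generator

The generator defines the study conditions.  Structural flags
(adult/engaged/diabetic status, exclusion reasons, ever-scorable status)
are planted with exact quotas (`round(rate·n)`), so attrition ground
truth is deterministic; per-year completeness, lab values, imaging and
cascade transitions are sampled.  Defaults: demographic mix Asian
0.36 / White 0.27 / Black 0.15 / Latinx 0.12 / Other 0.10, male 0.485,
public insurance 0.65; diabetes prevalence 0.12 among engaged adults;
exclusion rates HBV 0.030, HCV 0.025, AUD 0.0266 of the diabetic pool
(at n = 3297 these plant 99 + 82 + 88 = 269; the per-reason split is not
reported anywhere and is a generator choice); 73% of diabetic patients
ever scorable, 55% per-year completeness given scorable, 77% of complete
years also NFS-complete; imaging in 59% with 55% steatosis positivity;
cascade transition probabilities 0.56 / 0.79 / 1.0 / 0.76 / 0.87 / 0.885.

Lab values are drawn conditionally on a latent fibrosis propensity
z = 0.025·(age − 67) + N(0, 0.95): AST ~ lognormal(log 22 + 0.32 z, 0.30),
ALT ~ lognormal(log 24 + 0.08 z, 0.35), platelets ~ N(252 − 38 z, 52),
albumin ~ N(4.15 − 0.12 z, 0.30), HbA1c ~ N(7.2, 1.3) (≈ 27% at ≥ 8%),
BMI ~ N(29.8, 5.8) (N(27.2, 4.8) for Asian patients).  These center the
cohort near the observed summaries (median FIB-4 ≈ 1.3–1.4, mean ALT in
the normal range, platelets < 150 in roughly a tenth) while keeping the
score categories non-degenerate; they are approximate targets, not
calibration gates.  Decoy labs (earlier-in-year outpatient values, later
inpatient/emergency values) and decoy text (CT steatosis mentions,
negated phrasings) are planted so the last-of-year, setting and modality
rules are actually exercised.

The fibrosis outcome of staged patients follows
logit P(F3–4) = β₀ + β₁·1[HbA1c ≥ 8] + β₂·FIB-4 with defaults
β₁ = ln 7.02, β₂ = ln 1.79 (the reference multivariable odds ratios used
as true effects) and β₀ = −2.5, chosen so that staged-patient prevalence
sits near the observed ≈ 36% at typical covariate values.
`generate_association_cohort` exposes the same outcome model over
directly sampled covariates for parameter-recovery and type-I-error
simulations without full-extract overhead.

What the generator does not emulate: correlated repeat measurements
within a year, care-seeking intensity correlated with severity,
COVID-era availability shifts, coding error/noise, or realistic report
prose beyond short templates.  Passing tests therefore demonstrate that
the pipeline's rules are implemented correctly and recover planted
structure — not that the algorithm's clinical yield generalizes to any
particular health system.

## Numerical and presentation choices

Percent metrics round half-up (`Decimal`), one decimal for test
characteristics, whole percent for funnel yields, matching clinical
reporting convention (Python's built-in banker's rounding would differ at
exact halves).  The reference contingency table for the FIB-4 rule prints
a specificity of 59.0 alongside counts 26/44; 26/44 = 59.09 rounds to
59.1 under any rule consistent with the same table's other entries, so
the package asserts 59.1 from the counts.  Score-domain violations
(ALT ≤ 0, platelets ≤ 0) raise typed errors in the calculators and yield
absent scores in panel assembly.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
extracts.

## Problem sizes used in the test suite

Unit and property tests run on seeded synthetic extracts of 800 and 2000
patients; the cohort-scale checks use a 3297-patient diabetic extract;
recovery simulations use 100 replicates at n = 5000 and 200 null
replicates at n = 1000.  These sizes give stable binomial/coverage
margins for every assertion while keeping the default test run fast.

## Known limitations

- The discordance rule is a reconstruction validated against aggregate
  counts; alternative rules matching the same margins within ±1 exist.
- Keyword steatosis detection has no section awareness or grammar; a
  negated mention counts as positive under the default configuration.
- Covariate labs use outpatient values only, mirroring the score rules;
  deployments preferring all-setting covariates must adapt
  `stats_assoc._latest_value`.
- Radiological-cirrhosis evidence is accepted as a boolean assertion on
  the staging record; the package does not parse imaging text for it.
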