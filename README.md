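# casefinder

EMR-based case-finding for nonalcoholic fatty liver disease (NAFLD) with
advanced fibrosis in primary-care patients with diabetes.

Patients with type 2 diabetes carry a high burden of undiagnosed NAFLD, and
a meaningful fraction already have advanced fibrosis (METAVIR F3–4) —
the strongest predictor of liver-related complications.  `casefinder`
implements a screening algorithm a health system can run on routine EMR
data: assemble the diabetic cohort, compute blood-test fibrosis scores
from existing outpatient labs, flag high-risk patients for hepatology
referral, and account for what happens down the referral cascade.

## The algorithm

For every adult, actively engaged primary-care patient meeting a diabetes
criterion (problem-list ICD code, HbA1c ≥ 6.5% in the prior two years, or
an active antidiabetic medication) and free of competing liver disease
(detectable HBsAg, any prior detectable HCV RNA, or an alcohol-use-disorder
code), the pipeline computes per calendar year (2015–2020):

    FIB-4 = age · AST / (platelet · √ALT)
    NFS   = −1.675 + 0.037·age + 0.094·BMI + 1.13·DM
            + 0.99·AST/ALT − 0.013·platelet − 0.66·albumin

using, for each component independently, the **last outpatient value of the
calendar year** (emergency/inpatient labs never count; a year missing any
component yields no score).  The patient's highest FIB-4 and highest NFS
across years are categorized with age-based cutoffs (FIB-4 low < 1.3 under
65 / < 2.0 at 65+, high ≥ 2.67; NFS low < −1.455 / < 0.12, high > 0.676),
and a discordance rule produces the final risk group: FIB-4 is primary and
a high NFS bumps a non-high FIB-4 category up one level.  High-risk
patients under 75 who are alive and in the system form the intervention
target group; cascade accounting, fibrosis-outcome classification
(elastography LSM > 8 kPa, stage on MRE/biopsy, or radiological
cirrhosis), diagnostic performance (sens/spec/PPV/NPV) and logistic
risk-factor models complete the analysis.

A seeded synthetic EMR generator (`casefinder.synthetic_data`) emulates
the full data environment — longitudinal labs with per-year missingness,
comorbidity codes, ultrasound report text, stochastic cascade — with
ground-truth bookkeeping so the entire pipeline is testable end to end.

## Worked example

```python
from casefinder import CaseFindingModel
from casefinder.synthetic_data import GeneratorConfig, generate_extract, generate_cascade

config = GeneratorConfig(n_patients=3297, seed=17, adult_fraction=1.0,
                         engaged_fraction=1.0, dm_prevalence=1.0)
extract, truth = generate_extract(config)

model = CaseFindingModel(extract)
first = model.fit()                      # cohort, scores, risk groups, target

target = first.target.merge(first.assignments[["patient_id", "max_fib4"]],
                            on="patient_id")
target["hba1c_high"] = (truth.patients.set_index("patient_id")["hba1c_high"]
                        .reindex(target["patient_id"]).fillna(0).values)
events, staging, _ = generate_cascade(target, config, seed=17)
results = model.fit(cascade_events=events, staging_records=staging)
print(results.summary())
```

prints (abridged):

```
Patients in extract                3297
  excluded (HBV/HCV/AUD)       99/82/88
Final cohort                       3028

Risk groups (final)
  low             1051  (35%)
  indeterminate    462  (15%)
  high             716  (24%)
  unscorable       799  (26%)

Target group: 364 (high-risk 716, age-excluded 343, dead/departed 9)

Referral cascade
  messaged              364
  referred              208  (57% of previous)
  ...
  staging_completed     103  (92% of previous)
  advanced_fibrosis      54  (52% of previous)

Logistic models for advanced fibrosis (OR, 95% CI)
  [multi] hba1c_high                  7.14 (2.41-21.16)*
  [multi] fib4_max                    1.65 (1.10-2.47)*
```

Reading the output: of 3297 diabetic patients, 269 are excluded for HBV,
HCV or alcohol use disorder, leaving 3028; 26% lack complete components in
every calendar year and are unscorable; the rest split into low /
indeterminate / high risk.  The 364-patient target group flows down the
referral funnel with per-stage yields, and the multivariable logistic
model recovers the planted associations: poorly controlled diabetes
(HbA1c ≥ 8%, true OR 7.02) and FIB-4 (true OR 1.79 per unit) are the
independent predictors of advanced fibrosis.

A thin CLI wraps the same functions:

```bash
casefinder simulate --out extract/ --seed 17 --n-patients 2000
casefinder validate-extract extract/
casefinder run extract/ --out results/ --cascade-seed 17
```

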