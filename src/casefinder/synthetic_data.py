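"""Seeded synthetic EMR extracts and cascade streams with ground truth.

The generator emulates the data environment the pipeline assumes: a
multi-year outpatient laboratory stream with per-year missingness, a
diabetic subcohort with problem-list / HbA1c / medication evidence,
competing-liver-disease exclusions, templated ultrasound report text with
and without steatosis terms, a fibrosis outcome drawn from a logistic
model on glycemic control and FIB-4, and stochastic stage-to-stage
referral-cascade transitions.

Structural quantities (eligibility, exclusion reasons, per-year panel
completeness) are planted with exact quotas — ``round(rate * n)`` patients
get each flag — so the ground-truth bookkeeping is deterministic and the
deterministic pipeline stages can be checked for exact agreement.  Lab
values are drawn conditionally on a latent fibrosis propensity so that
higher propensity yields higher AST and AST:ALT ratio and lower
platelets, making the generated FIB-4/NFS categories non-degenerate.

Identical seeds produce byte-identical extracts.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .emr_model import EmrExtract
from .scores import (
    ScoreCutoffs, categorize_score, resolve_discordance, STUDY_YEARS,
)
from .cascade_metrics import STAGES, StagingRecord

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_extract",
    "generate_cascade",
    "generate_association_cohort",
]

ANCHOR = dt.date(2020, 7, 1)

#: templated ultrasound impressions; first group contains the detector terms
POSITIVE_TEMPLATES = (
    "Diffuse hepatic steatosis. Liver span normal.",
    "Increased hepatic echogenicity consistent with fatty liver.",
    "Mild steatosis of the liver. No focal lesion.",
    "Echogenic liver compatible with fatty liver disease.",
)
NEGATIVE_TEMPLATES = (
    "Normal liver echotexture. Cholelithiasis without cholecystitis.",
    "Unremarkable liver. Mild splenomegaly.",
    "Normal abdominal ultrasound examination.",
    "Simple hepatic cyst. Otherwise unremarkable liver.",
)
CT_STEATOSIS_TEMPLATE = (
    "CT abdomen: low attenuation liver suggestive of steatosis."
)

ANTIDIABETIC_DRUGS = ("metformin", "glipizide", "insulin glargine", "empagliflozin")


def _logit_inv(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic EMR generator.

    Defaults emulate the observed cohort: demographic mix and public-payer
    share of the practice's diabetic patients, 12% diabetes prevalence
    among engaged adults, per-reason exclusion rates totalling ~8.2% of
    the diabetic pool (269/3297 at paper scale), 73% of cohort patients
    with at least one scorable calendar year, 55% steatosis positivity
    among imaged patients, an outcome model with odds ratios 7.02 (HbA1c
    >= 8%) and 1.79 (per FIB-4 unit), and the observed stage-to-stage
    cascade proportions.
    """

    n_patients: int = 3297
    seed: int | None = None
    race_mix: dict = field(default_factory=lambda: {
        "Asian": 0.36, "White": 0.27, "Black": 0.15, "Latinx": 0.12, "Other": 0.10,
    })
    male_fraction: float = 0.485
    insurance_mix: dict = field(default_factory=lambda: {
        "public": 0.65, "private": 0.314, "uninsured": 0.036,
    })
    adult_fraction: float = 0.99
    engaged_fraction: float = 0.97
    dm_prevalence: float = 0.12
    exclusion_rates: dict = field(default_factory=lambda: {
        "HBV": 0.030, "HCV": 0.025, "AUD": 0.0266,
    })
    per_year_lab_availability: float = 0.73  # fraction of cohort ever scorable
    year_complete_p: float = 0.55            # per-year completeness if scorable
    nfs_given_fib4: float = 0.77             # albumin+BMI present per complete year
    imaging_rate: float = 0.59
    steatosis_prevalence: float = 0.55
    deceased_rate: float = 0.015
    departed_rate: float = 0.015
    mean_age: float = 66.0
    sd_age: float = 13.0
    outcome_beta0: float = -2.5
    outcome_beta_hba1c: float = math.log(7.02)
    outcome_beta_fib4: float = math.log(1.79)
    cascade_probs: dict = field(default_factory=lambda: {
        "referred": 0.56,
        "triage_accepted": 0.79,
        "scheduled": 1.0,
        "visit_completed": 0.76,
        "nafld_diagnosed": 0.87,
        "staging_completed": 0.885,
    })
    triage_not_nafld_share: float = 13 / 31  # of triage exits, vs needs-data
    modality_mix: dict = field(default_factory=lambda: {
        "TE": 51 / 69, "MRE": 6 / 69, "US_elastography": 5 / 69,
        "biopsy": 2 / 69, "clinical": 5 / 69,
    })
    study_years: tuple = STUDY_YEARS
    cutoffs: ScoreCutoffs = field(default_factory=ScoreCutoffs)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, mix in (("race_mix", self.race_mix),
                          ("insurance_mix", self.insurance_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
            if any(not 0 <= v <= 1 for v in mix.values()):
                raise ValueError(f"{name} proportions must be in [0, 1]")
        rates = [
            self.male_fraction, self.adult_fraction, self.engaged_fraction,
            self.dm_prevalence, self.per_year_lab_availability,
            self.year_complete_p, self.nfs_given_fib4, self.imaging_rate,
            self.steatosis_prevalence, self.deceased_rate, self.departed_rate,
            *self.exclusion_rates.values(), *self.cascade_probs.values(),
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates and probabilities must lie in [0, 1]")
        if sum(self.exclusion_rates.values()) > 1:
            raise ValueError("exclusion rates must not exceed 1 in total")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclass
class GroundTruth:
    """Generator-side bookkeeping consistent with the extract by construction."""

    patients: pd.DataFrame   # per-patient truth flags and categories
    panels: pd.DataFrame     # per patient-year planted components and scores
    attrition: dict          # expected cohort-builder attrition counts

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "attrition": self.attrition,
                "patients": self.patients.to_dict("records"),
                "panels": self.panels.to_dict("records"),
            },
            default=str,
        )


def _quota_flags(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Boolean vector with exactly round(rate*n) True, randomly placed."""
    k = int(math.floor(rate * n + 0.5))
    flags = np.zeros(n, dtype=bool)
    if k:
        flags[rng.choice(n, size=min(k, n), replace=False)] = True
    return flags


def _quota_labels(rng: np.random.Generator, n: int, mix: dict) -> np.ndarray:
    """Categorical vector honoring the mix with largest-remainder counts."""
    labels = list(mix)
    exact = [mix[l] * n for l in labels]
    counts = [int(math.floor(e)) for e in exact]
    order = sorted(range(len(labels)), key=lambda i: exact[i] - counts[i],
                   reverse=True)
    for i in range(n - sum(counts)):
        counts[order[i % len(labels)]] += 1
    out = np.repeat(labels, counts)
    rng.shuffle(out)
    return out


def _birth_date(age: int, rng: np.random.Generator) -> dt.date:
    base = dt.date(ANCHOR.year - int(age), ANCHOR.month, ANCHOR.day)
    return base - dt.timedelta(days=int(rng.integers(0, 365)))


def _day_in_year(year: int, lo: int, hi: int, rng: np.random.Generator) -> dt.date:
    # 2020 labs precede the July extraction date
    if year == 2020:
        hi = min(hi, 170)
        lo = min(lo, hi)
    day = int(rng.integers(lo, hi + 1))
    return dt.date(year, 1, 1) + dt.timedelta(days=day - 1)


def generate_extract(config: GeneratorConfig) -> tuple[EmrExtract, GroundTruth]:
    """Generate a full synthetic extract and its ground truth.

    Running the cohort and scoring stages on the extract reproduces the
    ground truth exactly for deterministic rules; sampled marginal rates
    agree with the configured values to binomial tolerance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:06d}" for i in range(1, n + 1)]

    race = _quota_labels(rng, n, config.race_mix)
    sex = np.where(_quota_flags(rng, n, config.male_fraction), "male", "female")
    insurance = _quota_labels(rng, n, config.insurance_mix)
    adult = _quota_flags(rng, n, config.adult_fraction)
    engaged = _quota_flags(rng, n, config.engaged_fraction)
    deceased = _quota_flags(rng, n, config.deceased_rate)
    departed = _quota_flags(rng, n, config.departed_rate)

    ages = np.clip(
        np.round(rng.normal(config.mean_age, config.sd_age, size=n)), 19, 95
    ).astype(int)
    ages[~adult] = rng.integers(8, 18, size=int((~adult).sum()))
    birth_dates = [_birth_date(a, rng) for a in ages]

    # diabetes among engaged adults; exclusions among that diabetic pool
    pool = adult & engaged
    diabetic = np.zeros(n, dtype=bool)
    pool_idx = np.flatnonzero(pool)
    dm_flags = _quota_flags(rng, len(pool_idx), config.dm_prevalence)
    diabetic[pool_idx[dm_flags]] = True

    excl_reason = np.array([None] * n, dtype=object)
    dm_idx = np.flatnonzero(diabetic)
    remaining = list(dm_idx)
    n_dm = len(dm_idx)
    for reason in ("HBV", "HCV", "AUD"):  # fixed order for determinism
        k = int(math.floor(config.exclusion_rates.get(reason, 0.0) * n_dm + 0.5))
        k = min(k, len(remaining))
        picked = rng.choice(len(remaining), size=k, replace=False)
        for i in sorted(picked, reverse=True):
            excl_reason[remaining[i]] = reason
            del remaining[i]

    eligible = diabetic & np.array([r is None for r in excl_reason])

    # latent fibrosis propensity drives the lab value gradients
    z = 0.025 * (ages - 67) + rng.normal(0.0, 0.95, size=n)

    scorable = np.zeros(n, dtype=bool)
    dm_all = np.flatnonzero(diabetic)
    sc_flags = _quota_flags(rng, len(dm_all), config.per_year_lab_availability)
    scorable[dm_all[sc_flags]] = True

    labs_rows: list[tuple] = []
    bmi_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    med_rows: list[tuple] = []
    enc_rows: list[tuple] = []
    img_rows: list[tuple] = []
    panel_rows: list[dict] = []
    truth_rows: list[dict] = []

    window_lo, window_hi = dt.date(2017, 7, 1), dt.date(2020, 6, 30)
    years = list(config.study_years)

    def add_lab(pid, analyte, value, date, setting="outpatient", detect=None):
        labs_rows.append((pid, analyte, value, detect, date, setting))

    for i in range(n):
        pid = pids[i]
        # encounters
        if engaged[i]:
            for _ in range(int(rng.integers(1, 4))):
                off = int(rng.integers(0, (window_hi - window_lo).days + 1))
                etype = "in_person_visit" if rng.random() < 0.7 else "patient_message"
                enc_rows.append((pid, etype, window_lo + dt.timedelta(days=off)))
        elif rng.random() < 0.7:
            off = int(rng.integers(30, 1500))
            enc_rows.append(
                (pid, "in_person_visit", window_lo - dt.timedelta(days=off))
            )

        bmi_base = (
            rng.normal(27.2, 4.8) if race[i] == "Asian" else rng.normal(29.8, 5.8)
        )
        bmi_base = float(np.clip(bmi_base, 16.0, 60.0))

        if not diabetic[i]:
            if adult[i] and rng.random() < 0.5:
                a1c = float(np.clip(rng.normal(5.7, 0.4), 4.5, 6.4))
                add_lab(pid, "HbA1c", round(a1c, 1),
                        _day_in_year(2019, 1, 360, rng))
            if adult[i] and rng.random() < 0.02:
                dx_rows.append((pid, "O24.419",
                                _day_in_year(2018, 1, 360, rng), True))
            truth_rows.append(dict(
                patient_id=pid, is_adult=bool(adult[i]),
                is_engaged=bool(engaged[i]), is_diabetic=False,
                excluded_reason=None, eligible=False, scorable=False,
                fib4_category="missing", nfs_category="missing",
                final_group="unscorable", max_fib4=None, max_nfs=None,
                imaged=False, steatosis_ultrasound=False, hba1c_high=None,
            ))
            continue

        # --- diabetic patient ---
        has_pl = rng.random() < 0.85
        has_med = rng.random() < 0.75
        if has_pl:
            code = "E11.9" if rng.random() < 0.9 else "250.00"
            dx_rows.append((pid, code, _day_in_year(2016, 1, 360, rng), True))
        if has_med:
            med_rows.append((pid, str(rng.choice(ANTIDIABETIC_DRUGS)), True, True))
        if rng.random() < 0.3:
            med_rows.append((pid, "lisinopril", False, True))
        if rng.random() < 0.8:  # hypertension codes mirror the cohort mix
            dx_rows.append((pid, "I10", _day_in_year(2017, 1, 360, rng), True))

        # annual HbA1c stream; force the lab arm if no other DM evidence
        a1c_vals = np.clip(rng.normal(7.2, 1.3, size=len(years)), 5.0, 14.0)
        if not (has_pl or has_med):
            a1c_vals[-1] = max(a1c_vals[-1], 6.6)
        last_a1c = None
        for yi, year in enumerate(years):
            if rng.random() < 0.8 or yi == len(years) - 1:
                d = _day_in_year(year, 150, 360, rng)
                add_lab(pid, "HbA1c", round(float(a1c_vals[yi]), 1), d)
                last_a1c = float(a1c_vals[yi])
        if not (has_pl or has_med) and last_a1c is not None and last_a1c < 6.5:
            add_lab(pid, "HbA1c", 6.6, dt.date(2020, 5, 15))
            last_a1c = 6.6

        # exclusion evidence and decoys
        reason = excl_reason[i]
        if reason == "HBV":
            add_lab(pid, "HBsAg", np.nan, _day_in_year(2012, 1, 360, rng),
                    detect="detectable")
        elif reason == "HCV":
            d0 = _day_in_year(2012, 1, 360, rng)
            add_lab(pid, "HCV_RNA", np.nan, d0, detect="detectable")
            if rng.random() < 0.5:  # cured later; still excluded
                add_lab(pid, "HCV_RNA", np.nan, _day_in_year(2018, 1, 360, rng),
                        detect="undetectable")
        elif reason == "AUD":
            add_lab(pid, "HBsAg", np.nan, _day_in_year(2015, 1, 360, rng),
                    detect="undetectable")
            dx_rows.append((pid, "F10.10", _day_in_year(2010, 1, 360, rng),
                            rng.random() < 0.5))
        else:
            if rng.random() < 0.2:
                add_lab(pid, "HBsAg", np.nan, _day_in_year(2016, 1, 360, rng),
                        detect="undetectable")
            if rng.random() < 0.1:
                add_lab(pid, "HCV_RNA", np.nan, _day_in_year(2017, 1, 360, rng),
                        detect="undetectable")

        # lipids (covariate labs)
        add_lab(pid, "triglyceride",
                round(float(np.clip(rng.normal(145, 60), 40, 600)), 0),
                _day_in_year(int(rng.choice([2018, 2019, 2020])), 1, 360, rng))
        add_lab(pid, "HDL", round(float(np.clip(rng.normal(47, 13), 15, 120)), 0),
                _day_in_year(int(rng.choice([2018, 2019, 2020])), 1, 360, rng))

        # ---- annual score panels ----
        if scorable[i]:
            complete = rng.random(len(years)) < config.year_complete_p
            if not complete.any():
                complete[int(rng.integers(0, len(years)))] = True
        else:
            complete = np.zeros(len(years), dtype=bool)
        nfs_complete = complete & (rng.random(len(years)) < config.nfs_given_fib4)

        max_fib4 = max_nfs = None
        max_fib4_year = max_nfs_year = None
        for yi, year in enumerate(years):
            age_dec31 = year - birth_dates[i].year
            if (birth_dates[i].month, birth_dates[i].day) > (12, 31):  # never
                age_dec31 -= 1
            ast = float(np.exp(rng.normal(math.log(22) + 0.32 * z[i], 0.30)))
            alt = float(np.exp(rng.normal(math.log(24) + 0.08 * z[i], 0.35)))
            plt_ = float(np.clip(rng.normal(252 - 38 * z[i], 52), 40, 600))
            alb = float(np.clip(rng.normal(4.15 - 0.12 * z[i], 0.30), 2.2, 5.2))
            bmi_y = float(np.clip(bmi_base + rng.normal(0, 0.6), 15.0, 60.0))
            ast, alt, plt_, alb = (
                round(ast, 0) or 1.0, round(alt, 0) or 1.0,
                round(plt_, 0), round(alb, 1),
            )
            bmi_y = round(bmi_y, 1)

            if complete[yi]:
                day_lo, day_hi = 200, 360
                d_ast = _day_in_year(year, day_lo, day_hi, rng)
                d_alt = _day_in_year(year, day_lo, day_hi, rng)
                d_plt = _day_in_year(year, day_lo, day_hi, rng)
                add_lab(pid, "AST", ast, d_ast)
                add_lab(pid, "ALT", alt, d_alt)
                add_lab(pid, "platelet", plt_, d_plt)
                if nfs_complete[yi]:
                    add_lab(pid, "albumin", alb, _day_in_year(year, day_lo, day_hi, rng))
                    bmi_rows.append((pid, bmi_y, _day_in_year(year, day_lo, day_hi, rng)))
                # decoys: earlier outpatient values and later non-outpatient
                if rng.random() < 0.35:
                    add_lab(pid, "AST", round(ast * 0.8, 0) or 1.0,
                            _day_in_year(year, 10, day_lo - 10, rng))
                if rng.random() < 0.15:
                    setting = "inpatient" if rng.random() < 0.5 else "emergency"
                    d_late = min(d_ast + dt.timedelta(days=3),
                                 dt.date(year, 12, 31))
                    add_lab(pid, "AST", round(ast * 2.5, 0), d_late,
                            setting=setting)

                fib4 = age_dec31 * ast / (plt_ * math.sqrt(alt))
                nfs = None
                if nfs_complete[yi]:
                    nfs = (
                        -1.675 + 0.037 * age_dec31 + 0.094 * bmi_y + 1.13
                        + 0.99 * ast / alt - 0.013 * plt_ - 0.66 * alb
                    )
                if max_fib4 is None or fib4 > max_fib4:
                    max_fib4, max_fib4_year = fib4, year
                if nfs is not None and (max_nfs is None or nfs > max_nfs):
                    max_nfs, max_nfs_year = nfs, year
                panel_rows.append(dict(
                    patient_id=pid, year=year, fib4_available=True,
                    nfs_available=bool(nfs_complete[yi]),
                    fib4=fib4, nfs=nfs,
                ))
            else:
                # incomplete year: drop >=1 FIB-4 component so no score exists
                keep = rng.random(3) < 0.5
                keep[int(rng.integers(0, 3))] = False
                day = _day_in_year(year, 30, 330, rng)
                for comp, val, k in (
                    ("AST", ast, keep[0]), ("ALT", alt, keep[1]),
                    ("platelet", plt_, keep[2]),
                ):
                    if k:
                        add_lab(pid, comp, val, day)
                panel_rows.append(dict(
                    patient_id=pid, year=year, fib4_available=False,
                    nfs_available=False, fib4=None, nfs=None,
                ))

        # truth categorization from the planted maxima
        fib4_cat = nfs_cat = "missing"
        if max_fib4 is not None:
            fib4_cat = categorize_score(
                max_fib4, "fib4", max_fib4_year - birth_dates[i].year,
                config.cutoffs,
            )
        if max_nfs is not None:
            nfs_cat = categorize_score(
                max_nfs, "nfs", max_nfs_year - birth_dates[i].year, config.cutoffs,
            )
        final = (
            "unscorable" if fib4_cat == "missing" and nfs_cat == "missing"
            else resolve_discordance(fib4_cat, nfs_cat)
        )

        # imaging
        imaged = rng.random() < config.imaging_rate
        steat = False
        if imaged:
            steat = rng.random() < config.steatosis_prevalence
            template_pool = POSITIVE_TEMPLATES if steat else NEGATIVE_TEMPLATES
            for _ in range(int(rng.integers(1, 3))):
                year_img = int(rng.integers(2000, 2021))
                img_rows.append((
                    pid, "ultrasound", _day_in_year(year_img, 1, 360, rng),
                    str(rng.choice(template_pool)),
                ))
            if not steat and rng.random() < 0.05:
                # CT mention must not flip the ultrasound-based flag
                img_rows.append((
                    pid, "CT", _day_in_year(2019, 1, 360, rng),
                    CT_STEATOSIS_TEMPLATE,
                ))

        truth_rows.append(dict(
            patient_id=pid, is_adult=bool(adult[i]), is_engaged=bool(engaged[i]),
            is_diabetic=True, excluded_reason=reason,
            eligible=bool(eligible[i]), scorable=bool(scorable[i]),
            fib4_category=fib4_cat, nfs_category=nfs_cat, final_group=final,
            max_fib4=max_fib4, max_nfs=max_nfs,
            imaged=imaged, steatosis_ultrasound=steat,
            hba1c_high=None if last_a1c is None else int(last_a1c >= 8.0),
        ))

    patients = pd.DataFrame({
        "patient_id": pids,
        "birth_date": pd.to_datetime(birth_dates),
        "sex": sex,
        "race_ethnicity": race,
        "insurance": insurance,
        "vital_status": np.where(deceased, "deceased", "alive"),
        "in_system": ~departed,
    })
    labs = pd.DataFrame(
        labs_rows,
        columns=["patient_id", "analyte", "value", "detectability",
                 "collection_date", "setting"],
    )
    labs["collection_date"] = pd.to_datetime(labs["collection_date"])
    labs["value"] = pd.to_numeric(labs["value"])
    diagnoses = pd.DataFrame(
        dx_rows, columns=["patient_id", "code", "code_date", "on_problem_list"]
    )
    diagnoses["code_date"] = pd.to_datetime(diagnoses["code_date"])
    medications = pd.DataFrame(
        med_rows, columns=["patient_id", "drug_class", "is_antidiabetic", "active"]
    )
    encounters = pd.DataFrame(
        enc_rows, columns=["patient_id", "event_type", "event_date"]
    )
    encounters["event_date"] = pd.to_datetime(encounters["event_date"])
    imaging = pd.DataFrame(
        img_rows, columns=["patient_id", "modality", "report_date", "report_text"]
    )
    imaging["report_date"] = pd.to_datetime(imaging["report_date"])
    bmi = pd.DataFrame(
        bmi_rows, columns=["patient_id", "bmi_value", "observation_date"]
    )
    bmi["observation_date"] = pd.to_datetime(bmi["observation_date"])

    extract = EmrExtract(
        patients=patients, labs=labs, diagnoses=diagnoses,
        medications=medications, encounters=encounters, imaging=imaging, bmi=bmi,
    )
    extract.validate()

    truth_patients = pd.DataFrame(truth_rows)
    excl_counts = (
        truth_patients.loc[
            truth_patients["excluded_reason"].notna(), "excluded_reason"
        ].value_counts().to_dict()
    )
    attrition = {
        "total": n,
        "adults": int(adult.sum()),
        "engaged": int((adult & engaged).sum()),
        "diabetic": int(diabetic.sum()),
        "excluded": {r: int(excl_counts.get(r, 0)) for r in ("HBV", "HCV", "AUD")},
        "final": int(truth_patients["eligible"].sum()),
    }
    truth = GroundTruth(
        patients=truth_patients,
        panels=pd.DataFrame(
            panel_rows,
            columns=["patient_id", "year", "fib4_available", "nfs_available",
                     "fib4", "nfs"],
        ),
        attrition=attrition,
    )
    return extract, truth


def generate_cascade(
    target: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[StagingRecord], pd.DataFrame]:
    """Stochastic referral cascade for the target group.

    ``target`` needs columns patient_id, max_fib4 and hba1c_high (0/1).
    Returns (event stream, staging records, true outcome table).  Stages
    are Bernoulli transitions with the configured probabilities; the
    fibrosis class of staged patients follows the logistic outcome model
    on glycemic control and maximum FIB-4.  The prefix invariant holds by
    construction.
    """
    if target.empty:
        raise ValueError("target list must be non-empty")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    p = config.cascade_probs
    mod_names = list(config.modality_mix)
    mod_probs = np.array([config.modality_mix[m] for m in mod_names], dtype=float)
    mod_probs = mod_probs / mod_probs.sum()

    events: list[tuple] = []
    staging: list[StagingRecord] = []
    outcome_rows: list[dict] = []

    for row in target.to_dict("records"):
        pid = row["patient_id"]
        fib4 = float(row.get("max_fib4") or 0.0)
        hba1c_high = int(row.get("hba1c_high") or 0)
        events.append((pid, "messaged", None, None))
        if rng.random() >= p["referred"]:
            continue
        if rng.random() >= p["triage_accepted"]:
            detail = (
                "triage_not_nafld"
                if rng.random() < config.triage_not_nafld_share
                else "triage_needs_data"
            )
            events.append((pid, "referred", detail, None))
            continue
        events.append((pid, "referred", None, None))
        events.append((pid, "triage_accepted", None, None))
        if rng.random() >= p["scheduled"]:
            continue
        events.append((pid, "scheduled", None, None))
        if rng.random() >= p["visit_completed"]:
            continue
        events.append((pid, "visit_completed", None, None))
        if rng.random() >= p["nafld_diagnosed"]:
            continue
        events.append((pid, "nafld_diagnosed", None, None))
        if rng.random() >= p["staging_completed"]:
            continue

        eta = (
            config.outcome_beta0
            + config.outcome_beta_hba1c * hba1c_high
            + config.outcome_beta_fib4 * fib4
        )
        f3_4 = rng.random() < _logit_inv(eta)
        modality = str(mod_names[rng.choice(len(mod_names), p=mod_probs)])
        rec = StagingRecord(patient_id=pid, modality=modality)
        if modality in ("TE", "US_elastography"):
            if f3_4:
                rec.lsm_kpa = round(float(10.5 + rng.exponential(5.0)), 1)
            else:
                rec.lsm_kpa = round(float(rng.uniform(3.5, 7.9)), 1)
        elif modality in ("MRE", "biopsy"):
            rec.fibrosis_stage = int(rng.choice([3, 4]) if f3_4
                                     else rng.choice([0, 1, 2]))
        else:  # clinical
            rec.asserted_f3_4 = bool(f3_4)
            if f3_4 and rng.random() < 0.2:
                rec.radiological_cirrhosis = True
        staging.append(rec)
        events.append((pid, "staging_completed", modality, rec.lsm_kpa))
        if f3_4:
            events.append((pid, "advanced_fibrosis", None, None))
        outcome_rows.append(dict(
            patient_id=pid, stage_class="F3_4" if f3_4 else "F0_2",
            basis="radiological_cirrhosis" if rec.radiological_cirrhosis
            else modality,
        ))

    events_df = pd.DataFrame(
        events, columns=["patient_id", "stage", "stage_detail", "lsm_kpa"]
    )
    outcomes = pd.DataFrame(
        outcome_rows, columns=["patient_id", "stage_class", "basis"]
    )
    return events_df, staging, outcomes


def generate_association_cohort(
    n: int,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    null: bool = False,
) -> pd.DataFrame:
    """Covariate vectors with an outcome drawn from the generator's
    logistic model (the lightweight path for parameter-recovery and
    type-I-error simulations).

    With ``null=True`` every coefficient is zero (intercept only), so any
    fitted association is spurious.
    """
    config = config or GeneratorConfig(seed=0)
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    race = rng.choice(
        list(config.race_mix), size=n, p=list(config.race_mix.values())
    )
    bmi_mix = {"normal": 0.157, "underweight": 0.01, "overweight": 0.237,
               "obese": 0.596}
    data = pd.DataFrame({
        "male": rng.binomial(1, config.male_fraction, size=n),
        "race_ethnicity": race,
        "bmi_class": rng.choice(list(bmi_mix), size=n, p=list(bmi_mix.values())),
        "hba1c_high": rng.binomial(1, 0.26, size=n),
        "fib4_max": np.clip(rng.normal(2.4, 0.8, size=n), 0.3, None),
    })
    if null:
        eta = np.full(n, math.log(0.36 / 0.64))
    else:
        eta = (
            config.outcome_beta0
            + config.outcome_beta_hba1c * data["hba1c_high"].to_numpy()
            + config.outcome_beta_fib4 * data["fib4_max"].to_numpy()
        )
    data["f3_4"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    return data
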