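"""Eligibility and exclusion rules producing the analyzable diabetic cohort.

The cohort is every adult patient actively engaged in primary care who
meets at least one diabetes criterion (active problem-list code, HbA1c at
or above threshold within the lookback, or an active antidiabetic
medication) and has no evidence of a competing chronic liver disease
(detectable HBsAg, any prior detectable HCV RNA, or an alcohol-use-disorder
code, evaluated over the entire record with no time restriction).

Code sets default to broad ICD-9/10 prefixes (E10/E11/250 for diabetes,
O24/R73/E09 for the excluded diabetes types, F10/303/305.0 for alcohol use
disorder) and are fully configurable; a study substituting its curated
lists supplies them through :class:`CohortConfig` (YAML supported via
``CohortConfig.from_yaml``).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

from .emr_model import EmrExtract, age_on

__all__ = [
    "CohortConfig",
    "EligibilityResult",
    "is_actively_engaged",
    "is_diabetic",
    "has_exclusionary_liver_disease",
    "build_cohort",
]

#: fixed precedence for single-reason attrition reporting
EXCLUSION_PRECEDENCE = ("HBV", "HCV", "AUD")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of cohort assembly.

    ``engagement_window`` bounds the active-engagement lookback (inclusive);
    ``hba1c_lookback_years`` and ``hba1c_threshold`` parameterize the
    laboratory diabetes criterion, measured back from ``anchor_date`` (the
    extract date), mirroring assembly-time phrasing of "in the prior
    2 years".
    """

    engagement_window: tuple[dt.date, dt.date] = (
        dt.date(2017, 7, 1),
        dt.date(2020, 6, 30),
    )
    hba1c_lookback_years: int = 2
    hba1c_threshold: float = 6.5
    dm_code_prefixes: tuple[str, ...] = ("E10", "E11", "250")
    dm_exclusion_code_prefixes: tuple[str, ...] = ("O24", "648.8", "R73", "E09", "249")
    aud_code_prefixes: tuple[str, ...] = ("F10", "303", "305.0")
    anchor_date: dt.date = dt.date(2020, 7, 1)

    def __post_init__(self):
        lo, hi = self.engagement_window
        if pd.Timestamp(lo) > pd.Timestamp(hi):
            raise ValueError("engagement_window is not well-ordered")
        if self.hba1c_threshold <= 0 or self.hba1c_lookback_years <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "engagement_window" in raw:
            raw["engagement_window"] = tuple(
                dt.date.fromisoformat(str(d)) for d in raw["engagement_window"]
            )
        if "anchor_date" in raw:
            raw["anchor_date"] = dt.date.fromisoformat(str(raw["anchor_date"]))
        for key in ("dm_code_prefixes", "dm_exclusion_code_prefixes", "aud_code_prefixes"):
            if key in raw:
                raw[key] = tuple(str(c) for c in raw[key])
        return cls(**raw)


@dataclass
class EligibilityResult:
    patient_id: str
    is_adult: bool
    is_engaged: bool
    is_diabetic: bool
    dm_criteria_met: frozenset[str]
    excluded_reason: str | None  # {HBV, HCV, AUD, dm_type_exclusion}

    @property
    def eligible(self) -> bool:
        return (
            self.is_adult
            and self.is_engaged
            and self.is_diabetic
            and self.excluded_reason is None
        )


def _matches_prefix(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    codes = codes.astype(str)
    out = pd.Series(False, index=codes.index)
    for p in prefixes:
        out |= codes.str.startswith(p)
    return out


def is_actively_engaged(
    encounters: pd.DataFrame, window: tuple[dt.date, dt.date]
) -> bool:
    """True iff the patient has >=1 in-person visit or patient-initiated
    message with event_date inside the window (inclusive endpoints)."""
    if encounters.empty:
        return False
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    d = pd.to_datetime(encounters["event_date"])
    return bool(((d >= lo) & (d <= hi)).any())


def is_diabetic(
    codes: pd.DataFrame,
    labs: pd.DataFrame,
    meds: pd.DataFrame,
    config: CohortConfig,
) -> tuple[bool, frozenset[str]]:
    """Evaluate the three diabetes criteria for one patient.

    Returns (diabetic, criteria met); ``criteria`` lists every satisfied arm
    of {problem_list_code, hba1c, medication}.  Codes belonging to the
    excluded diabetes types (gestational, steroid-induced, prediabetes)
    never satisfy the problem-list arm.
    """
    met: set[str] = set()

    if not codes.empty:
        on_pl = codes["on_problem_list"].astype(bool)
        dm = _matches_prefix(codes["code"], config.dm_code_prefixes)
        excl = _matches_prefix(codes["code"], config.dm_exclusion_code_prefixes)
        if bool((on_pl & dm & ~excl).any()):
            met.add("problem_list_code")

    if not labs.empty:
        anchor = pd.Timestamp(config.anchor_date)
        lookback = anchor - pd.DateOffset(years=config.hba1c_lookback_years)
        a1c = labs[labs["analyte"] == "HbA1c"]
        if not a1c.empty:
            d = pd.to_datetime(a1c["collection_date"])
            hit = (
                (a1c["value"] >= config.hba1c_threshold)
                & (d >= lookback)
                & (d <= anchor)
            )
            if bool(hit.any()):
                met.add("hba1c")

    if not meds.empty:
        if bool((meds["is_antidiabetic"] & meds["active"]).any()):
            met.add("medication")

    return bool(met), frozenset(met)


def has_exclusionary_liver_disease(
    labs: pd.DataFrame, codes: pd.DataFrame, config: CohortConfig
) -> str | None:
    """First applicable exclusion reason (HBV > HCV > AUD precedence),
    evaluated over the patient's entire record with no time restriction.

    A detectable HCV RNA at any time excludes even if later undetectable;
    diagnosis codes are never used for HBV/HCV (labs only), only for
    alcohol use disorder.
    """
    reasons = _liver_exclusion_reasons(labs, codes, config)
    for reason in EXCLUSION_PRECEDENCE:
        if reason in reasons:
            return reason
    return None


def _liver_exclusion_reasons(
    labs: pd.DataFrame, codes: pd.DataFrame, config: CohortConfig
) -> set[str]:
    reasons: set[str] = set()
    if not labs.empty:
        det = labs["detectability"] == "detectable"
        if bool(((labs["analyte"] == "HBsAg") & det).any()):
            reasons.add("HBV")
        if bool(((labs["analyte"] == "HCV_RNA") & det).any()):
            reasons.add("HCV")
    if not codes.empty:
        if bool(_matches_prefix(codes["code"], config.aud_code_prefixes).any()):
            reasons.add("AUD")
    return reasons


def build_cohort(
    extract: EmrExtract, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, list[EligibilityResult], dict]:
    """Apply eligibility and exclusion filters to the whole extract.

    Returns (cohort table, per-patient eligibility results, attrition
    summary).  The attrition summary reports counts surviving each filter
    in sequence (adults -> engaged -> diabetic -> post-exclusion) plus the
    per-reason exclusion tally; filters commute, the sequence is a
    reporting convention.
    """
    config = config or CohortConfig()
    patients = extract.patients
    by_pid = {
        name: dict(tuple(t.groupby("patient_id", sort=False)))
        for name, t in (
            ("labs", extract.labs),
            ("diagnoses", extract.diagnoses),
            ("medications", extract.medications),
            ("encounters", extract.encounters),
        )
    }
    empty = {name: getattr(extract, name).iloc[0:0] for name in by_pid}

    results: list[EligibilityResult] = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        labs = by_pid["labs"].get(pid, empty["labs"])
        codes = by_pid["diagnoses"].get(pid, empty["diagnoses"])
        meds = by_pid["medications"].get(pid, empty["medications"])
        encs = by_pid["encounters"].get(pid, empty["encounters"])

        adult = age_on(row.birth_date, config.anchor_date) >= 18
        engaged = is_actively_engaged(encs, config.engagement_window)
        diabetic, criteria = is_diabetic(codes, labs, meds, config)
        reason = has_exclusionary_liver_disease(labs, codes, config)
        if reason is None and not diabetic and not codes.empty:
            # evidence restricted to an excluded diabetes type is recorded
            if bool(
                _matches_prefix(codes["code"], config.dm_exclusion_code_prefixes).any()
            ):
                reason = "dm_type_exclusion"
        results.append(
            EligibilityResult(pid, adult, engaged, diabetic, criteria, reason)
        )

    res = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "is_adult": [r.is_adult for r in results],
            "is_engaged": [r.is_engaged for r in results],
            "is_diabetic": [r.is_diabetic for r in results],
            "excluded_reason": [r.excluded_reason for r in results],
            "eligible": [r.eligible for r in results],
        }
    )
    adults = res["is_adult"]
    engaged = adults & res["is_engaged"]
    diabetic = engaged & res["is_diabetic"]
    liver_excluded = diabetic & res["excluded_reason"].isin(EXCLUSION_PRECEDENCE)
    excl_counts = (
        res.loc[liver_excluded, "excluded_reason"].value_counts().to_dict()
    )
    attrition = {
        "total": int(len(res)),
        "adults": int(adults.sum()),
        "engaged": int(engaged.sum()),
        "diabetic": int(diabetic.sum()),
        "excluded": {r: int(excl_counts.get(r, 0)) for r in EXCLUSION_PRECEDENCE},
        "final": int(res["eligible"].sum()),
    }
    cohort = (
        patients[patients["patient_id"].isin(res.loc[res["eligible"], "patient_id"])]
        .reset_index(drop=True)
    )
    return cohort, results, attrition
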