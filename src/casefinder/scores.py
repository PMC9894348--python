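"""Annual FIB-4 / NFS computation, risk categorization, discordance resolution.

Per calendar year of the study period (2015-2020 by default), each score
is computed from the last outpatient measurement of each component within
that year ("last of year"), components taken independently so they may
come from different dates; emergency-department and inpatient values are
never used.  A year missing any component yields no score for that year.
The patient's highest FIB-4 and highest NFS across years (not necessarily
the same year) are categorized with age-based cutoffs and combined into a
final risk group by a discordance-resolution rule.

Score formulas are the canonical published closed forms::

    FIB-4 = age * AST / (platelet * sqrt(ALT))
    NFS   = -1.675 + 0.037*age + 0.094*BMI + 1.13*DM
            + 0.99*AST/ALT - 0.013*platelet - 0.66*albumin

with AST/ALT in IU/L, platelets in 10^9/L, albumin in g/dL, BMI in kg/m2.

The default discordance rule treats FIB-4 as primary: a missing NFS defers
to the FIB-4 category, concordant categories pass through, and a high NFS
bumps a non-high FIB-4 category up exactly one level (low->indeterminate,
indeterminate->high); all other discordance defers to FIB-4.  The rule is
pluggable via the ``resolver`` argument of :func:`assign_risk_groups`.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emr_model import EmrExtract, age_on

__all__ = [
    "ScoreCutoffs",
    "AnnualScorePanel",
    "RiskAssignment",
    "UndefinedScoreError",
    "fib4_score",
    "nfs_score",
    "last_of_year_components",
    "annual_scores",
    "highest_scores",
    "categorize_score",
    "resolve_discordance",
    "assign_risk_groups",
    "STUDY_YEARS",
    "RISK_LEVELS",
]

STUDY_YEARS: tuple[int, ...] = tuple(range(2015, 2021))
RISK_LEVELS = ("low", "indeterminate", "high")

#: lab analytes entering the score panels (BMI comes from its own table)
PANEL_ANALYTES = ("AST", "ALT", "platelet", "albumin")


class UndefinedScoreError(ValueError):
    """Score requested with inputs outside its domain (e.g. ALT = 0)."""


@dataclass(frozen=True)
class ScoreCutoffs:
    """Age-stratified category cutoffs.

    Defaults are the widely used age-adjusted thresholds: FIB-4 low below
    1.3 under age 65 / below 2.0 at 65+, high at >= 2.67; NFS low below
    -1.455 / below 0.12, high above 0.676.  All configurable.
    """

    fib4_low_lt_under65: float = 1.3
    fib4_low_lt_65plus: float = 2.0
    fib4_high_ge: float = 2.67
    nfs_low_lt_under65: float = -1.455
    nfs_low_lt_65plus: float = 0.12
    nfs_high_gt: float = 0.676
    age_pivot: int = 65

    def __post_init__(self):
        if not (self.fib4_low_lt_under65 < self.fib4_high_ge
                and self.fib4_low_lt_65plus < self.fib4_high_ge):
            raise ValueError("FIB-4 low cutoffs must lie below the high cutoff")
        if not (self.nfs_low_lt_under65 < self.nfs_high_gt
                and self.nfs_low_lt_65plus < self.nfs_high_gt):
            raise ValueError("NFS low cutoffs must lie below the high cutoff")


@dataclass
class AnnualScorePanel:
    """Last-of-year component set and resulting scores for one patient-year."""

    patient_id: str
    year: int
    ast: float | None = None
    alt: float | None = None
    platelet: float | None = None
    albumin: float | None = None
    bmi: float | None = None
    dm_flag: int = 1
    component_dates: dict = field(default_factory=dict)
    age_at_panel: int | None = None
    fib4: float | None = None
    nfs: float | None = None


@dataclass
class RiskAssignment:
    patient_id: str
    max_fib4: float | None = None
    max_fib4_year: int | None = None
    max_nfs: float | None = None
    max_nfs_year: int | None = None
    fib4_category: str = "missing"
    nfs_category: str = "missing"
    final_group: str = "unscorable"


def fib4_score(age: float, ast: float, alt: float, platelet: float) -> float:
    """FIB-4 = age * AST / (platelet * sqrt(ALT))."""
    if alt <= 0 or platelet <= 0:
        raise UndefinedScoreError(
            f"FIB-4 undefined for ALT={alt}, platelet={platelet}"
        )
    if age <= 0 or ast < 0:
        raise UndefinedScoreError(f"FIB-4 undefined for age={age}, AST={ast}")
    return age * ast / (platelet * math.sqrt(alt))


def nfs_score(
    age: float, bmi: float, dm_flag: int, ast: float, alt: float,
    platelet: float, albumin: float,
) -> float:
    """NAFLD Fibrosis Score (linear form; see module docstring for units)."""
    if alt <= 0:
        raise UndefinedScoreError(f"NFS undefined for ALT={alt}")
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * dm_flag
        + 0.99 * (ast / alt)
        - 0.013 * platelet
        - 0.66 * albumin
    )


def last_of_year_components(
    labs: pd.DataFrame, bmi_obs: pd.DataFrame, year: int,
) -> dict[str, tuple[float, dt.date]]:
    """Per component independently, the outpatient measurement with the
    latest collection date within the calendar year.

    Same-date duplicates are broken toward the larger value (conservative
    toward detection).  Emergency/inpatient labs never contribute.  Absent
    components are absent from the returned mapping.
    """
    out: dict[str, tuple[float, dt.date]] = {}
    if not labs.empty:
        d = pd.to_datetime(labs["collection_date"])
        sel = labs[
            (labs["setting"] == "outpatient")
            & (d.dt.year == year)
            & labs["analyte"].isin(PANEL_ANALYTES)
        ]
        if not sel.empty:
            sel = sel.sort_values(["collection_date", "value"], kind="stable")
            last = sel.groupby("analyte").tail(1)
            for row in last.itertuples(index=False):
                out[row.analyte] = (
                    float(row.value),
                    pd.Timestamp(row.collection_date).date(),
                )
    if bmi_obs is not None and not bmi_obs.empty:
        d = pd.to_datetime(bmi_obs["observation_date"])
        sel = bmi_obs[d.dt.year == year]
        if not sel.empty:
            sel = sel.sort_values(["observation_date", "bmi_value"], kind="stable")
            row = sel.iloc[-1]
            out["bmi"] = (
                float(row["bmi_value"]),
                pd.Timestamp(row["observation_date"]).date(),
            )
    return out


def _panel_scores(panel: AnnualScorePanel) -> None:
    """Fill fib4/nfs in place from present components (absent if incomplete
    or outside the score domain)."""
    have_fib4 = (
        panel.ast is not None
        and panel.alt is not None and panel.alt > 0
        and panel.platelet is not None and panel.platelet > 0
    )
    if have_fib4:
        panel.fib4 = fib4_score(panel.age_at_panel, panel.ast, panel.alt, panel.platelet)
        if panel.albumin is not None and panel.bmi is not None:
            panel.nfs = nfs_score(
                panel.age_at_panel, panel.bmi, panel.dm_flag,
                panel.ast, panel.alt, panel.platelet, panel.albumin,
            )


def annual_scores(
    labs: pd.DataFrame,
    bmi_obs: pd.DataFrame,
    birth_date,
    patient_id: str = "",
    study_years: tuple[int, ...] = STUDY_YEARS,
    dm_flag: int = 1,
) -> list[AnnualScorePanel]:
    """One panel per study year; scores absent where components incomplete.

    ``age_at_panel`` is the age on Dec 31 of the panel year, anchoring each
    annual panel to its own calendar year.
    """
    panels = []
    for year in study_years:
        comp = last_of_year_components(labs, bmi_obs, year)
        panel = AnnualScorePanel(
            patient_id=patient_id,
            year=year,
            ast=comp.get("AST", (None, None))[0],
            alt=comp.get("ALT", (None, None))[0],
            platelet=comp.get("platelet", (None, None))[0],
            albumin=comp.get("albumin", (None, None))[0],
            bmi=comp.get("bmi", (None, None))[0],
            dm_flag=dm_flag,
            component_dates={k: v[1] for k, v in comp.items()},
            age_at_panel=age_on(birth_date, dt.date(year, 12, 31)),
        )
        _panel_scores(panel)
        panels.append(panel)
    return panels


def highest_scores(panels: list[AnnualScorePanel]) -> RiskAssignment:
    """Maximum per score across years, independently; the two maxima need
    not come from the same year.  No scorable year -> unscorable."""
    if not panels:
        return RiskAssignment(patient_id="")
    ra = RiskAssignment(patient_id=panels[0].patient_id)
    for p in panels:
        if p.fib4 is not None and (ra.max_fib4 is None or p.fib4 > ra.max_fib4):
            ra.max_fib4, ra.max_fib4_year = p.fib4, p.year
        if p.nfs is not None and (ra.max_nfs is None or p.nfs > ra.max_nfs):
            ra.max_nfs, ra.max_nfs_year = p.nfs, p.year
    return ra


def categorize_score(
    score: float, score_kind: str, age: float, cutoffs: ScoreCutoffs | None = None
) -> str:
    """Categorize one score given the age stratum (age at the year of the
    patient's maximum score): high first (FIB-4 >= high cutoff; NFS > high
    cutoff), then low below the age-appropriate low cutoff, else
    indeterminate."""
    cutoffs = cutoffs or ScoreCutoffs()
    senior = age >= cutoffs.age_pivot
    if score_kind == "fib4":
        if score >= cutoffs.fib4_high_ge:
            return "high"
        low = cutoffs.fib4_low_lt_65plus if senior else cutoffs.fib4_low_lt_under65
        return "low" if score < low else "indeterminate"
    if score_kind == "nfs":
        if score > cutoffs.nfs_high_gt:
            return "high"
        low = cutoffs.nfs_low_lt_65plus if senior else cutoffs.nfs_low_lt_under65
        return "low" if score < low else "indeterminate"
    raise ValueError(f"unknown score_kind {score_kind!r}")


def resolve_discordance(fib4_category: str, nfs_category: str) -> str:
    """Combine the two categories into the final risk group (default rule).

    FIB-4 is primary; a high NFS bumps a non-high FIB-4 up exactly one
    level; all other discordance defers to FIB-4.  Raises if both are
    missing (the caller marks such patients unscorable).
    """
    if fib4_category == "missing" and nfs_category == "missing":
        raise ValueError("both categories missing: patient is unscorable")
    if fib4_category == "missing":
        return nfs_category
    if nfs_category == "missing" or nfs_category == fib4_category:
        return fib4_category
    if nfs_category == "high" and fib4_category != "high":
        return RISK_LEVELS[RISK_LEVELS.index(fib4_category) + 1]
    return fib4_category


def _assign_one(
    labs, bmi_obs, birth_date, patient_id, study_years, cutoffs, resolver
) -> RiskAssignment:
    panels = annual_scores(labs, bmi_obs, birth_date, patient_id, study_years)
    ra = highest_scores(panels)
    ra.patient_id = patient_id
    if ra.max_fib4 is not None:
        age = age_on(birth_date, dt.date(ra.max_fib4_year, 12, 31))
        ra.fib4_category = categorize_score(ra.max_fib4, "fib4", age, cutoffs)
    if ra.max_nfs is not None:
        age = age_on(birth_date, dt.date(ra.max_nfs_year, 12, 31))
        ra.nfs_category = categorize_score(ra.max_nfs, "nfs", age, cutoffs)
    if ra.fib4_category == "missing" and ra.nfs_category == "missing":
        ra.final_group = "unscorable"
    else:
        ra.final_group = resolver(ra.fib4_category, ra.nfs_category)
    return ra


def assign_risk_groups(
    extract: EmrExtract,
    cohort: pd.DataFrame,
    cutoffs: ScoreCutoffs | None = None,
    study_years: tuple[int, ...] = STUDY_YEARS,
    resolver=resolve_discordance,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient risk assignments for the cohort plus the NFS-by-FIB-4
    category crosstab (rows: NFS low/indeterminate/high/missing; columns:
    FIB-4 low/indeterminate/high; marginals included).

    Patients with neither score are ``unscorable`` and appear in neither
    crosstab margin; crosstab marginals sum to the scored-cohort size.
    """
    cutoffs = cutoffs or ScoreCutoffs()
    labs_by = dict(tuple(extract.labs.groupby("patient_id", sort=False)))
    bmi_by = dict(tuple(extract.bmi.groupby("patient_id", sort=False)))
    empty_labs = extract.labs.iloc[0:0]
    empty_bmi = extract.bmi.iloc[0:0]

    rows = []
    for row in cohort.itertuples(index=False):
        pid = row.patient_id
        ra = _assign_one(
            labs_by.get(pid, empty_labs), bmi_by.get(pid, empty_bmi),
            row.birth_date, pid, study_years, cutoffs, resolver,
        )
        rows.append(
            {
                "patient_id": pid,
                "max_fib4": ra.max_fib4,
                "max_fib4_year": ra.max_fib4_year,
                "max_nfs": ra.max_nfs,
                "max_nfs_year": ra.max_nfs_year,
                "fib4_category": ra.fib4_category,
                "nfs_category": ra.nfs_category,
                "final_group": ra.final_group,
            }
        )
    assignments = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "max_fib4", "max_fib4_year", "max_nfs",
            "max_nfs_year", "fib4_category", "nfs_category", "final_group",
        ],
    )
    crosstab = category_crosstab(assignments)
    return assignments, crosstab


def category_crosstab(assignments: pd.DataFrame) -> pd.DataFrame:
    """NFS-by-FIB-4 category table with marginals, over scored patients."""
    scored = assignments[assignments["final_group"] != "unscorable"]
    nfs_order = ["low", "indeterminate", "high", "missing"]
    fib4_order = ["low", "indeterminate", "high"]
    tab = pd.crosstab(scored["nfs_category"], scored["fib4_category"])
    tab = tab.reindex(index=nfs_order, columns=fib4_order, fill_value=0).astype(int)
    tab.index.name = "nfs_category"
    tab.columns.name = "fib4_category"
    tab["total"] = tab.sum(axis=1)
    tab.loc["total"] = tab.sum(axis=0)
    return tab
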