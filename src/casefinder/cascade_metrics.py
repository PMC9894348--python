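"""Referral-cascade accounting and diagnostic performance of high-risk scores.

The intervention funnel is an ordered stage sequence

    messaged -> referred -> triage_accepted -> scheduled -> visit_completed
    -> nafld_diagnosed -> staging_completed -> advanced_fibrosis

and a patient's recorded stages must form a prefix of it.  The ledger
reports the count reaching each stage and the stage-to-stage proportion
(whole percent, against the immediately preceding stage).

Fibrosis outcomes classify staged patients as F3-4 (advanced fibrosis or
cirrhosis) vs F0-2 using a liver-stiffness threshold for elastography
(default LSM > 8 kPa), the reported stage for MR elastography or biopsy,
definitive radiological cirrhosis, or a direct clinical assessment.
Performance of the high-risk score rules (high FIB-4, high NFS, both) is
tabulated over staged patients only.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .emr_model import age_on

__all__ = [
    "STAGES",
    "StagingRecord",
    "FibrosisOutcome",
    "PerformanceTable",
    "CascadeOrderError",
    "select_target_group",
    "classify_fibrosis_outcome",
    "cascade_ledger",
    "performance_metrics",
    "sample_for_validation",
    "round_half_up",
]

STAGES: tuple[str, ...] = (
    "messaged",
    "referred",
    "triage_accepted",
    "scheduled",
    "visit_completed",
    "nafld_diagnosed",
    "staging_completed",
    "advanced_fibrosis",
)

TRIAGE_EXIT_DETAILS = ("triage_not_nafld", "triage_needs_data")
STAGING_MODALITIES = ("TE", "MRE", "US_elastography", "biopsy", "clinical")


class CascadeOrderError(Exception):
    """A patient's recorded stages are not a prefix of the stage order."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the presentation convention for metrics;
    Python's built-in round is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StagingRecord:
    """Fibrosis-staging evidence for one patient."""

    patient_id: str
    modality: str | None = None  # TE, MRE, US_elastography, biopsy, clinical
    lsm_kpa: float | None = None
    fibrosis_stage: int | None = None  # METAVIR 0-4, for MRE/biopsy
    radiological_cirrhosis: bool = False
    asserted_f3_4: bool | None = None  # for modality == "clinical"


@dataclass
class FibrosisOutcome:
    patient_id: str
    stage_class: str  # {F3_4, F0_2, unstaged}
    basis: str | None = None


@dataclass
class PerformanceTable:
    """2x2 counts and the derived test characteristics, in percent to one
    decimal (half-up); a zero denominator yields ``None``, never 0."""

    tp: int
    fp: int
    tn: int
    fn: int

    def _pct(self, num: int, den: int) -> float | None:
        if den == 0:
            return None
        return round_half_up(100.0 * num / den, 1)

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def n_staged(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
        }


def select_target_group(
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    anchor_date: dt.date,
    age_limit: int = 75,
) -> tuple[pd.DataFrame, dict]:
    """Intervention target group: high-risk, age strictly below the limit
    at the anchor date, alive and still in the system.

    Returns the target patient table and a tally of removals
    (age first, then death/departure among the remainder).
    """
    high = assignments.loc[assignments["final_group"] == "high", "patient_id"]
    pool = patients[patients["patient_id"].isin(high)].copy()
    ages = pd.Series(
        [age_on(b, anchor_date) for b in pool["birth_date"]],
        index=pool.index, dtype=float,
    )
    age_ok = ages < age_limit
    n_age_excluded = int((~age_ok).sum())
    pool = pool[age_ok]
    alive_in = (pool["vital_status"] == "alive") & pool["in_system"].astype(bool)
    n_dead_departed = int((~alive_in).sum())
    target = pool[alive_in].reset_index(drop=True)
    tally = {
        "high_risk": int(len(high)),
        "age_excluded": n_age_excluded,
        "dead_or_departed": n_dead_departed,
        "target": int(len(target)),
    }
    return target, tally


def classify_fibrosis_outcome(
    record: StagingRecord, lsm_threshold_kpa: float = 8.0
) -> FibrosisOutcome:
    """Classify one staged patient as F3-4 vs F0-2.

    F3-4 iff elastography LSM strictly above the threshold, MRE/biopsy
    stage in {3, 4}, definitive radiological cirrhosis, or a clinical
    F3-4 assertion; an absent modality (and no radiological cirrhosis)
    yields ``unstaged``.
    """
    pid = record.patient_id
    if record.radiological_cirrhosis:
        return FibrosisOutcome(pid, "F3_4", basis="radiological_cirrhosis")
    if record.modality is None:
        return FibrosisOutcome(pid, "unstaged")
    if record.modality in ("TE", "US_elastography"):
        if record.lsm_kpa is None:
            return FibrosisOutcome(pid, "unstaged")
        cls = "F3_4" if record.lsm_kpa > lsm_threshold_kpa else "F0_2"
        return FibrosisOutcome(pid, cls, basis=record.modality)
    if record.modality in ("MRE", "biopsy"):
        if record.fibrosis_stage is None:
            return FibrosisOutcome(pid, "unstaged")
        cls = "F3_4" if record.fibrosis_stage >= 3 else "F0_2"
        return FibrosisOutcome(pid, cls, basis=record.modality)
    if record.modality == "clinical":
        if record.asserted_f3_4 is None:
            return FibrosisOutcome(pid, "unstaged")
        return FibrosisOutcome(
            pid, "F3_4" if record.asserted_f3_4 else "F0_2", basis="clinical"
        )
    raise ValueError(f"unknown staging modality {record.modality!r}")


def cascade_ledger(
    events: pd.DataFrame, target_ids: list[str] | pd.Series
) -> pd.DataFrame:
    """Per-stage counts through the funnel with stage-to-stage proportions.

    ``events`` has columns (patient_id, stage[, stage_detail, lsm_kpa]).
    Each patient's stage set must be a prefix of :data:`STAGES`; a
    violation raises :class:`CascadeOrderError` naming the patient.
    Proportions are against the immediately preceding stage, whole
    percent, half-up; the first stage and stages with an empty
    predecessor have no proportion.
    """
    target_ids = list(target_ids)
    stage_index = {s: i for i, s in enumerate(STAGES)}
    unknown = set(events["stage"]) - set(STAGES) if len(events) else set()
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    events = events[events["patient_id"].isin(target_ids)]

    reached = {s: 0 for s in STAGES}
    for pid, grp in events.groupby("patient_id", sort=False):
        idx = sorted(stage_index[s] for s in set(grp["stage"]))
        if idx != list(range(len(idx))):
            missing = STAGES[[i for i in range(len(STAGES)) if i not in idx][0]]
            raise CascadeOrderError(
                f"patient {pid}: stage set skips '{missing}' (not a prefix)"
            )
        for i in idx:
            reached[STAGES[i]] += 1

    counts = [reached[s] for s in STAGES]
    pcts: list[float | None] = [None]
    for prev, cur in zip(counts, counts[1:]):
        pcts.append(round_half_up(100.0 * cur / prev, 0) if prev else None)
    ledger = pd.DataFrame(
        {"stage": STAGES, "count": counts, "pct_of_previous": pcts}
    )
    return ledger


def performance_metrics(
    assignments: pd.DataFrame,
    outcomes: pd.DataFrame,
    score_rule: str,
) -> PerformanceTable:
    """Tabulate one high-risk score rule against staged fibrosis outcomes.

    ``score_rule`` is one of ``fib4_high``, ``nfs_high``, ``both_high``;
    positives are patients whose relevant max-score category is "high".
    Only staged patients (stage_class F3_4 or F0_2) enter the table.
    """
    merged = outcomes.merge(assignments, on="patient_id", how="inner")
    staged = merged[merged["stage_class"].isin(["F3_4", "F0_2"])]
    fib4_high = staged["fib4_category"] == "high"
    nfs_high = staged["nfs_category"] == "high"
    if score_rule == "fib4_high":
        called = fib4_high
    elif score_rule == "nfs_high":
        called = nfs_high
    elif score_rule == "both_high":
        called = fib4_high & nfs_high
    else:
        raise ValueError(f"unknown score_rule {score_rule!r}")
    diseased = staged["stage_class"] == "F3_4"
    return PerformanceTable(
        tp=int((called & diseased).sum()),
        fp=int((called & ~diseased).sum()),
        tn=int((~called & ~diseased).sum()),
        fn=int((~called & diseased).sum()),
    )


def sample_for_validation(
    high_risk_ids: list[str], fraction: float = 0.10, seed: int | None = None
) -> list[str]:
    """Simple random sample without replacement of round(fraction * n)
    patients, reproducible under ``seed`` (used for manual chart review of
    the high-risk group)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = list(high_risk_ids)
    if not ids:
        raise ValueError("high_risk_ids must be non-empty")
    k = int(math.floor(fraction * len(ids) + 0.5))
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(picked)]
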