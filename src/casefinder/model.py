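"""Model/Results facade over the case-finding pipeline.

:class:`CaseFindingModel` is built from an EMR extract plus the study
configuration; :meth:`CaseFindingModel.fit` runs cohort assembly, annual
FIB-4/NFS scoring, risk categorization, steatosis text review and target
selection, and — when a cascade event stream and staging records are
supplied — referral-funnel accounting, fibrosis outcome classification,
score performance and the logistic risk-factor models.  The returned
:class:`CaseFindingResults` carries every intermediate table and renders a
text ``summary()``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from . import cascade_metrics, cohort as cohort_mod, scores as scores_mod
from .cascade_metrics import (
    PerformanceTable, cascade_ledger, classify_fibrosis_outcome,
    performance_metrics, select_target_group,
)
from .cohort import CohortConfig, build_cohort
from .emr_model import EmrExtract, read_emr_extract
from .scores import ScoreCutoffs, assign_risk_groups
from .steatosis_text import patient_ever_steatosis
from .stats_assoc import build_covariate_table, fit_models

__all__ = ["CaseFindingModel", "CaseFindingResults"]


class CaseFindingModel:
    """Case-finding algorithm for NAFLD with advanced fibrosis, applied to
    a primary-care diabetes population.

    Parameters
    ----------
    extract : EmrExtract
        The full EMR extract (see :mod:`casefinder.emr_model`).
    cohort_config : CohortConfig, optional
        Eligibility/exclusion parameters; defaults to the study window.
    cutoffs : ScoreCutoffs, optional
        Age-based score category cutoffs.
    target_age_limit : int
        Strict upper age bound for the intervention target group.
    """

    def __init__(
        self,
        extract: EmrExtract,
        cohort_config: CohortConfig | None = None,
        cutoffs: ScoreCutoffs | None = None,
        target_age_limit: int = 75,
    ):
        self.extract = extract
        self.cohort_config = cohort_config or CohortConfig()
        self.cutoffs = cutoffs or ScoreCutoffs()
        self.target_age_limit = target_age_limit

    @classmethod
    def from_directory(cls, path, **kwargs) -> "CaseFindingModel":
        cfg = kwargs.get("cohort_config") or CohortConfig()
        extract = read_emr_extract(path, anchor_date=None)
        return cls(extract, **kwargs)

    def fit(
        self,
        cascade_events: pd.DataFrame | None = None,
        staging_records: list | None = None,
        fit_associations: bool = True,
    ) -> "CaseFindingResults":
        extract = self.extract
        cohort, eligibility, attrition = build_cohort(extract, self.cohort_config)
        assignments, crosstab = assign_risk_groups(
            extract, cohort, cutoffs=self.cutoffs
        )

        img_by = dict(tuple(extract.imaging.groupby("patient_id", sort=False)))
        empty_img = extract.imaging.iloc[0:0]
        steatosis = {
            pid: patient_ever_steatosis(img_by.get(pid, empty_img))
            for pid in cohort["patient_id"]
        }

        target, target_tally = select_target_group(
            assignments, extract.patients,
            anchor_date=self.cohort_config.anchor_date,
            age_limit=self.target_age_limit,
        )

        ledger = None
        outcomes = None
        performance: dict[str, PerformanceTable] = {}
        associations = None
        association_info = None
        if cascade_events is not None:
            ledger = cascade_ledger(cascade_events, list(target["patient_id"]))
        if staging_records:
            outcomes = pd.DataFrame(
                [vars(classify_fibrosis_outcome(r)) for r in staging_records]
            )
            performance = {
                rule: performance_metrics(assignments, outcomes, rule)
                for rule in ("fib4_high", "nfs_high", "both_high")
            }
            if fit_associations:
                staged = outcomes[outcomes["stage_class"].isin(["F3_4", "F0_2"])]
                cov = build_covariate_table(
                    extract,
                    assignments[assignments["patient_id"].isin(staged["patient_id"])],
                    self.cohort_config.anchor_date,
                    steatosis_flags=steatosis,
                )
                cov = cov.merge(
                    staged.assign(f3_4=(staged["stage_class"] == "F3_4").astype(int))[
                        ["patient_id", "f3_4"]
                    ],
                    on="patient_id",
                )
                if cov["f3_4"].nunique() >= 2:
                    associations, association_info = fit_models(cov)

        return CaseFindingResults(
            model=self,
            cohort=cohort,
            eligibility=eligibility,
            attrition=attrition,
            assignments=assignments,
            crosstab=crosstab,
            steatosis=steatosis,
            target=target,
            target_tally=target_tally,
            ledger=ledger,
            outcomes=outcomes,
            performance=performance,
            associations=associations,
            association_info=association_info,
        )


@dataclass
class CaseFindingResults:
    """Fitted pipeline outputs; see :class:`CaseFindingModel`."""

    model: CaseFindingModel
    cohort: pd.DataFrame
    eligibility: list
    attrition: dict
    assignments: pd.DataFrame
    crosstab: pd.DataFrame
    steatosis: dict
    target: pd.DataFrame
    target_tally: dict
    ledger: pd.DataFrame | None = None
    outcomes: pd.DataFrame | None = None
    performance: dict = field(default_factory=dict)
    associations: list | None = None
    association_info: dict | None = None

    @property
    def risk_group_counts(self) -> pd.Series:
        order = ["low", "indeterminate", "high", "unscorable"]
        return (
            self.assignments["final_group"].value_counts().reindex(order, fill_value=0)
        )

    def summary(self) -> str:
        a = self.attrition
        lines = [
            "Case-finding summary",
            "=" * 64,
            f"Patients in extract            {a['total']:>8}",
            f"  adults                       {a['adults']:>8}",
            f"  actively engaged             {a['engaged']:>8}",
            f"  diabetic                     {a['diabetic']:>8}",
            f"  excluded (HBV/HCV/AUD)       "
            f"{a['excluded']['HBV']}/{a['excluded']['HCV']}/{a['excluded']['AUD']}",
            f"Final cohort                   {a['final']:>8}",
            "",
            "Risk groups (final)",
        ]
        counts = self.risk_group_counts
        scored = int(counts[["low", "indeterminate", "high"]].sum())
        for grp in ("low", "indeterminate", "high", "unscorable"):
            pct = 100.0 * counts[grp] / max(len(self.assignments), 1)
            lines.append(f"  {grp:<13} {int(counts[grp]):>6}  ({pct:.0f}%)")
        lines.append(f"  scored        {scored:>6}")
        t = self.target_tally
        lines += [
            "",
            f"Target group: {t['target']} "
            f"(high-risk {t['high_risk']}, age-excluded {t['age_excluded']}, "
            f"dead/departed {t['dead_or_departed']})",
        ]
        if self.ledger is not None:
            lines += ["", "Referral cascade"]
            for row in self.ledger.itertuples(index=False):
                pct = "" if pd.isna(row.pct_of_previous) else (
                    f"  ({row.pct_of_previous:.0f}% of previous)"
                )
                lines.append(f"  {row.stage:<18} {row.count:>6}{pct}")
        if self.performance:
            lines += ["", "Performance of high-risk score rules (staged patients)"]
            for rule, tab in self.performance.items():
                lines.append(
                    f"  {rule:<10} sens {tab.sensitivity} spec {tab.specificity} "
                    f"ppv {tab.ppv} npv {tab.npv} "
                    f"(tp/fp/tn/fn {tab.tp}/{tab.fp}/{tab.tn}/{tab.fn})"
                )
        if self.associations:
            lines += ["", "Logistic models for advanced fibrosis (OR, 95% CI)"]
            for r in self.associations:
                if not pd.notna(r.odds_ratio):
                    lines.append(f"  [{r.mode[:5]}] {r.term:<24} -- {r.note}")
                    continue
                star = "*" if r.significant else " "
                lines.append(
                    f"  [{r.mode[:5]}] {r.term:<24} "
                    f"{r.odds_ratio:7.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}){star}"
                )
        return "\n".join(lines)

    def plot_funnel(self, ax=None):
        """Horizontal bar chart of the referral funnel (requires a fitted
        ledger)."""
        if self.ledger is None:
            raise ValueError("no cascade events were fitted")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        led = self.ledger
        ax.barh(range(len(led))[::-1], led["count"], color="#31688e")
        ax.set_yticks(range(len(led))[::-1], led["stage"])
        ax.set_xlabel("patients reaching stage")
        for i, c in enumerate(led["count"]):
            ax.text(c, len(led) - 1 - i, f" {c}", va="center")
        return ax
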