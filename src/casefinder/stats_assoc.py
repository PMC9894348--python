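"""Covariate recoding and logistic risk-factor models for advanced fibrosis.

Covariates follow the study definitions: binary indicators at HbA1c >= 8%,
HDL < 40, triglycerides >= 150, platelets < 150; BMI classed with
Asian-specific cutpoints (18.5 / 23 / 27) for Asian patients and WHO
cutpoints (18.5 / 25 / 30) otherwise; FIB-4 enters as a continuous
per-patient value (the maximum across study years by default, with a
policy switch); NFS is deliberately excluded from the models because of
its collinearity with FIB-4.

Bivariable models fit each predictor alone; the multivariable model fits a
fixed term set (sex, race/ethnicity, BMI class, glycemic control, FIB-4).
Odds ratios are exponentiated coefficients with Wald 95% confidence
intervals on the log-odds scale.  Fitting is delegated to
``statsmodels``; separation or non-convergence is flagged on the result
rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "BMI_CLASSES",
    "bmi_class",
    "recode_covariates",
    "build_covariate_table",
    "fit_models",
    "variance_inflation_report",
    "DEFAULT_MULTIVARIABLE_TERMS",
]

BMI_CLASSES = ("underweight", "normal", "overweight", "obese")

#: reference level per categorical term (fixed by the analysis design)
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "race_ethnicity": ["White", "Black", "Latinx", "Asian", "Other"],
    "insurance": ["public", "private", "uninsured"],
    "bmi_class": ["normal", "underweight", "overweight", "obese"],
}

DEFAULT_MULTIVARIABLE_TERMS = (
    "male", "race_ethnicity", "bmi_class", "hba1c_high", "fib4_max",
)

BINARY_TERMS = (
    "male", "hypertension", "hba1c_high", "triglyceride_high",
    "hdl_low", "platelet_low", "steatosis_imaging",
)


@dataclass
class AssociationResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    mode: str  # {bivariable, multivariable}
    significant: bool
    converged: bool = True
    note: str | None = None


def bmi_class(bmi: float, is_asian: bool) -> str:
    """BMI class with population-specific cutpoints, lower bound inclusive.

    Asian: normal 18.5-22.9, overweight 23-26.9, obese >= 27;
    non-Asian: normal 18.5-24.9, overweight 25-29.9, obese >= 30;
    underweight < 18.5 for both.
    """
    lo, mid, hi = (18.5, 23.0, 27.0) if is_asian else (18.5, 25.0, 30.0)
    if bmi < lo:
        return "underweight"
    if bmi < mid:
        return "normal"
    if bmi < hi:
        return "overweight"
    return "obese"


def _latest_value(labs: pd.DataFrame, analyte: str, anchor_date) -> float | None:
    """Most recent qualifying outpatient value on or before the anchor."""
    sel = labs[(labs["analyte"] == analyte) & (labs["setting"] == "outpatient")]
    if sel.empty:
        return None
    d = pd.to_datetime(sel["collection_date"])
    sel = sel[d <= pd.Timestamp(anchor_date)]
    if sel.empty:
        return None
    sel = sel.sort_values(["collection_date", "value"], kind="stable")
    return float(sel["value"].iloc[-1])


def recode_covariates(
    patient_row,
    assignment_row,
    labs: pd.DataFrame,
    bmi_obs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    anchor_date,
    steatosis_imaging: bool = False,
    age: int | None = None,
    fib4_policy: str = "max",
    hypertension_prefixes: tuple[str, ...] = ("I10", "I11", "I12", "I13", "401", "402", "403", "404"),
) -> dict:
    """One patient's covariate vector (dict of CovariateVector fields).

    Threshold indicators use the most recent qualifying lab at or before
    the anchor date; missing labs yield ``None`` (complete-case handling
    happens at fit time, with dropped-row counts logged).  NFS is never
    emitted.  ``fib4_policy`` selects which per-patient FIB-4 enters the
    model: ``max`` (default), ``median`` or ``last`` of the annual values.
    """
    hba1c = _latest_value(labs, "HbA1c", anchor_date)
    trig = _latest_value(labs, "triglyceride", anchor_date)
    hdl = _latest_value(labs, "HDL", anchor_date)
    plt_ = _latest_value(labs, "platelet", anchor_date)

    bmi_val = None
    if bmi_obs is not None and not bmi_obs.empty:
        sel = bmi_obs[pd.to_datetime(bmi_obs["observation_date"]) <= pd.Timestamp(anchor_date)]
        if not sel.empty:
            sel = sel.sort_values(["observation_date", "bmi_value"], kind="stable")
            bmi_val = float(sel["bmi_value"].iloc[-1])

    htn = False
    if diagnoses is not None and not diagnoses.empty:
        codes = diagnoses["code"].astype(str)
        htn = bool(
            np.logical_or.reduce(
                [codes.str.startswith(p) for p in hypertension_prefixes]
            ).any()
        )

    if fib4_policy == "max":
        fib4 = assignment_row.get("max_fib4")
    elif fib4_policy in ("median", "last"):
        vals = assignment_row.get("annual_fib4") or []
        vals = [v for v in vals if v is not None]
        if not vals:
            fib4 = None
        else:
            fib4 = float(np.median(vals)) if fib4_policy == "median" else vals[-1]
    else:
        raise ValueError(f"unknown fib4_policy {fib4_policy!r}")
    if fib4 is not None and pd.isna(fib4):
        fib4 = None

    is_asian = patient_row["race_ethnicity"] == "Asian"
    return {
        "patient_id": patient_row["patient_id"],
        "age": age,
        "male": int(patient_row["sex"] == "male"),
        "race_ethnicity": patient_row["race_ethnicity"],
        "insurance": patient_row["insurance"],
        "bmi_class": None if bmi_val is None else bmi_class(bmi_val, is_asian),
        "hypertension": int(htn),
        "hba1c_high": None if hba1c is None else int(hba1c >= 8.0),
        "fib4_max": fib4,
        "triglyceride_high": None if trig is None else int(trig >= 150),
        "hdl_low": None if hdl is None else int(hdl < 40),
        "platelet_low": None if plt_ is None else int(plt_ < 150),
        "steatosis_imaging": int(bool(steatosis_imaging)),
    }


def build_covariate_table(
    extract, assignments: pd.DataFrame, anchor_date,
    steatosis_flags: dict[str, bool] | None = None,
    fib4_policy: str = "max",
) -> pd.DataFrame:
    """Covariate vectors for every assigned patient, as a DataFrame."""
    from .emr_model import age_on

    steatosis_flags = steatosis_flags or {}
    labs_by = dict(tuple(extract.labs.groupby("patient_id", sort=False)))
    bmi_by = dict(tuple(extract.bmi.groupby("patient_id", sort=False)))
    dx_by = dict(tuple(extract.diagnoses.groupby("patient_id", sort=False)))
    empty_labs = extract.labs.iloc[0:0]
    empty_bmi = extract.bmi.iloc[0:0]
    empty_dx = extract.diagnoses.iloc[0:0]
    pat = extract.patients.set_index("patient_id", drop=False)

    rows = []
    for arow in assignments.to_dict("records"):
        pid = arow["patient_id"]
        prow = pat.loc[pid]
        rows.append(
            recode_covariates(
                prow, arow,
                labs_by.get(pid, empty_labs),
                bmi_by.get(pid, empty_bmi),
                dx_by.get(pid, empty_dx),
                anchor_date,
                steatosis_imaging=steatosis_flags.get(pid, False),
                age=age_on(prow["birth_date"], anchor_date),
                fib4_policy=fib4_policy,
            )
        )
    return pd.DataFrame(rows)


def _design_block(data: pd.DataFrame, term: str) -> pd.DataFrame:
    """Design columns for one term (dummy block for categoricals with the
    fixed reference level dropped)."""
    if term in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[term]
        cat = pd.Categorical(data[term], categories=levels)
        dummies = pd.get_dummies(cat, prefix=term, dtype=float)
        return dummies.drop(columns=f"{term}_{levels[0]}").set_axis(data.index)
    return data[[term]].astype(float)


def _fit_logit(y: pd.Series, X: pd.DataFrame, mode: str) -> list[AssociationResult]:
    results: list[AssociationResult] = []
    # a level unobserved in the analysis sample is not estimable; dropping
    # its all-zero dummy keeps the remaining fit well-posed
    degenerate = [c for c in X.columns if X[c].nunique() <= 1]
    for c in degenerate:
        results.append(
            AssociationResult(c, np.nan, np.nan, np.nan, np.nan, mode, False,
                              converged=False,
                              note="not estimable: no variation in sample")
        )
    X = X.drop(columns=degenerate)
    if X.empty or X.shape[1] == 0:
        return results
    X = sm.add_constant(X, has_constant="add")
    converged, note = True, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # pragma: no cover - pathological input
            return results + [
                AssociationResult(c, np.nan, np.nan, np.nan, np.nan, mode,
                                  False, converged=False, note=str(exc))
                for c in X.columns if c != "const"
            ]
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    pvals = np.asarray(fit.pvalues)
    conf = np.asarray(fit.conf_int(alpha=0.05))
    out = results
    conf = np.clip(conf, -700, 700)  # effectively unbounded CI stays finite
    for i, name in enumerate(X.columns):
        if name == "const":
            continue
        huge = not np.isfinite(bse[i]) or bse[i] > 50 or abs(params[i]) > 15
        out.append(
            AssociationResult(
                term=name,
                odds_ratio=float(np.exp(params[i])),
                ci_low=float(np.exp(conf[i][0])),
                ci_high=float(np.exp(conf[i][1])),
                p_value=float(pvals[i]),
                mode=mode,
                significant=bool(pvals[i] < 0.05),
                converged=converged and not huge,
                note="possible separation or non-convergence"
                if (huge or not converged) else None,
            )
        )
    return out


def fit_models(
    data: pd.DataFrame,
    outcome: str = "f3_4",
    bivariable_terms: tuple[str, ...] | None = None,
    multivariable_terms: tuple[str, ...] = DEFAULT_MULTIVARIABLE_TERMS,
) -> tuple[list[AssociationResult], dict]:
    """Bivariable and multivariable logistic models for the F3-4 outcome.

    Returns (results, info); ``info`` logs complete-case drop counts per
    model.  Requires at least one event and one non-event.
    """
    y_all = data[outcome]
    if y_all.nunique() < 2:
        raise ValueError("outcome must have at least one event and one non-event")
    if bivariable_terms is None:
        bivariable_terms = tuple(
            t for t in (
                "age", "male", "race_ethnicity", "insurance", "bmi_class",
                "hypertension", "hba1c_high", "fib4_max", "triglyceride_high",
                "hdl_low", "platelet_low", "steatosis_imaging",
            ) if t in data.columns
        )
    results: list[AssociationResult] = []
    dropped: dict[str, int] = {}

    for term in bivariable_terms:
        sub = data[[outcome, term]].dropna()
        dropped[f"bivariable:{term}"] = int(len(data) - len(sub))
        if sub[outcome].nunique() < 2 or len(sub) == 0:
            continue
        X = _design_block(sub, term)
        results.extend(_fit_logit(sub[outcome], X, "bivariable"))

    cols = [outcome] + list(multivariable_terms)
    sub = data[cols].dropna()
    dropped["multivariable"] = int(len(data) - len(sub))
    if sub[outcome].nunique() >= 2 and len(sub):
        X = pd.concat([_design_block(sub, t) for t in multivariable_terms], axis=1)
        results.extend(_fit_logit(sub[outcome], X, "multivariable"))

    return results, {"dropped_rows": dropped, "n": int(len(data))}


def variance_inflation_report(
    data: pd.DataFrame, terms: tuple[str, ...] = DEFAULT_MULTIVARIABLE_TERMS
) -> pd.DataFrame:
    """Advisory collinearity screen: variance inflation factor per design
    column of the multivariable term set (complete cases)."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    sub = data[list(terms)].dropna()
    X = pd.concat([_design_block(sub, t) for t in terms], axis=1)
    X = sm.add_constant(X, has_constant="add")
    arr = np.asarray(X, dtype=float)
    rows = [
        {"term": name, "vif": float(variance_inflation_factor(arr, i))}
        for i, name in enumerate(X.columns)
        if name != "const"
    ]
    return pd.DataFrame(rows)
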