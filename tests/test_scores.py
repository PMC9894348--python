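import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casefinder.cohort import build_cohort
from casefinder.emr_model import age_on
from casefinder.scores import (
    RISK_LEVELS,
    STUDY_YEARS,
    ScoreCutoffs,
    UndefinedScoreError,
    annual_scores,
    assign_risk_groups,
    categorize_score,
    fib4_score,
    highest_scores,
    last_of_year_components,
    nfs_score,
    resolve_discordance,
)

CUT = ScoreCutoffs()


# ---------------------------------------------------------------- calculators

def test_fib4_hand_examples():
    assert fib4_score(61, 40, 40, 100) == pytest.approx(3.8580, abs=1e-3)
    assert fib4_score(61, 40, 40, 200) == pytest.approx(1.9290, abs=1e-3)
    assert fib4_score(61, 0, 40, 100) == 0.0


def test_nfs_hand_examples():
    assert nfs_score(60, 30, 1, 40, 40, 200, 4.0) == pytest.approx(0.245, abs=1e-3)
    assert nfs_score(60, 30, 1, 40, 40, 200, 5.0) == pytest.approx(-0.415, abs=1e-3)
    d = nfs_score(60, 30, 1, 40, 40, 200, 4.0) - nfs_score(60, 30, 0, 40, 40, 200, 4.0)
    assert d == pytest.approx(1.13, abs=1e-12)


def test_randomized_inputs_match_hand_arithmetic_oracle():
    """Both calculators agree with independently coded formulas on >=20
    random inputs."""
    rng = np.random.default_rng(314)
    for _ in range(25):
        age = rng.uniform(20, 90)
        ast = rng.uniform(5, 300)
        alt = rng.uniform(5, 300)
        plt_ = rng.uniform(50, 450)
        alb = rng.uniform(2.0, 5.5)
        bmi = rng.uniform(16, 50)
        dm = int(rng.integers(0, 2))
        # oracle: term-by-term hand arithmetic
        fib4_oracle = (age * ast) / (plt_ * alt ** 0.5)
        nfs_oracle = sum([
            -1.675, 0.037 * age, 0.094 * bmi, 1.13 * dm, 0.99 * ast / alt,
            -0.013 * plt_, -0.66 * alb,
        ])
        assert fib4_score(age, ast, alt, plt_) == pytest.approx(fib4_oracle, abs=1e-3)
        assert nfs_score(age, bmi, dm, ast, alt, plt_, alb) == pytest.approx(
            nfs_oracle, abs=1e-3
        )


@pytest.mark.parametrize("arg", ["alt", "platelet"])
def test_fib4_undefined_for_nonpositive_denominator(arg):
    kwargs = dict(age=61, ast=40, alt=40, platelet=100)
    kwargs[arg] = 0
    with pytest.raises(UndefinedScoreError):
        fib4_score(**kwargs)
    with pytest.raises(UndefinedScoreError):
        nfs_score(60, 30, 1, 40, 0, 200, 4.0)


def test_nfs_finite_differences_equal_coefficients():
    base = dict(age=55, bmi=28, dm_flag=1, ast=30, alt=30, platelet=220, albumin=4.2)
    coef = {"age": 0.037, "bmi": 0.094, "dm_flag": 1.13, "platelet": -0.013,
            "albumin": -0.66}
    y0 = nfs_score(**base)
    for name, c in coef.items():
        bumped = dict(base, **{name: base[name] + 1})
        assert nfs_score(**bumped) - y0 == pytest.approx(c, abs=1e-9)


@given(
    age=st.floats(20, 90), ast=st.floats(1, 400), alt=st.floats(1, 400),
    plt_=st.floats(40, 500),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_fib4_monotonicity(age, ast, alt, plt_):
    """Strictly increasing in age and AST; strictly decreasing in platelets
    and ALT."""
    base = fib4_score(age, ast, alt, plt_)
    assert fib4_score(age + 1, ast, alt, plt_) >= base
    assert fib4_score(age, ast + 1, alt, plt_) >= base
    assert fib4_score(age, ast, alt + 1, plt_) <= base
    assert fib4_score(age, ast, alt, plt_ + 1) <= base


# --------------------------------------------------------- last-of-year rules

def _labs(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "analyte", "value", "detectability",
                 "collection_date", "setting"],
    )


def _bmi(rows):
    return pd.DataFrame(rows, columns=["patient_id", "bmi_value", "observation_date"])


def test_latest_outpatient_value_of_the_year_wins():
    labs = _labs([
        ("p", "AST", 30.0, None, pd.Timestamp("2018-03-03"), "outpatient"),
        ("p", "AST", 44.0, None, pd.Timestamp("2018-11-20"), "outpatient"),
    ])
    comp = last_of_year_components(labs, _bmi([]), 2018)
    assert comp["AST"] == (44.0, dt.date(2018, 11, 20))


def test_components_may_come_from_different_dates():
    labs = _labs([
        ("p", "AST", 30.0, None, pd.Timestamp("2018-02-01"), "outpatient"),
        ("p", "ALT", 25.0, None, pd.Timestamp("2018-12-30"), "outpatient"),
    ])
    comp = last_of_year_components(labs, _bmi([]), 2018)
    assert comp["AST"][1] == dt.date(2018, 2, 1)
    assert comp["ALT"][1] == dt.date(2018, 12, 30)


def test_inpatient_and_emergency_values_never_used():
    labs = _labs([
        ("p", "platelet", 90.0, None, pd.Timestamp("2018-12-30"), "inpatient"),
        ("p", "AST", 90.0, None, pd.Timestamp("2018-12-31"), "emergency"),
    ])
    assert last_of_year_components(labs, _bmi([]), 2018) == {}


def test_same_date_tie_broken_toward_larger_value():
    labs = _labs([
        ("p", "AST", 33.0, None, pd.Timestamp("2018-06-06"), "outpatient"),
        ("p", "AST", 55.0, None, pd.Timestamp("2018-06-06"), "outpatient"),
    ])
    assert last_of_year_components(labs, _bmi([]), 2018)["AST"][0] == 55.0


def test_annual_scores_counts_and_component_independence():
    birth = dt.date(1955, 4, 1)
    rows = []
    for year in (2016, 2019):
        for analyte, value in (("AST", 30.0), ("ALT", 28.0), ("platelet", 210.0)):
            rows.append(("p", analyte, value, None,
                         pd.Timestamp(dt.date(year, 11, 1)), "outpatient"))
    panels = annual_scores(_labs(rows), _bmi([]), birth, "p")
    assert len(panels) == len(STUDY_YEARS)
    with_fib4 = [p for p in panels if p.fib4 is not None]
    assert {p.year for p in with_fib4} == {2016, 2019}
    # albumin never measured: no NFS anywhere, FIB-4 unaffected
    assert all(p.nfs is None for p in panels)
    assert panels[1].age_at_panel == age_on(birth, dt.date(2016, 12, 31))


def test_highest_scores_max_years_are_independent():
    birth = dt.date(1950, 1, 15)
    rows = []
    # 2017: big FIB-4 (low platelets), no NFS; 2019: complete panel
    for analyte, value in (("AST", 80.0), ("ALT", 30.0), ("platelet", 90.0)):
        rows.append(("p", analyte, value, None, pd.Timestamp("2017-10-01"), "outpatient"))
    for analyte, value in (("AST", 30.0), ("ALT", 30.0), ("platelet", 240.0),
                           ("albumin", 3.0)):
        rows.append(("p", analyte, value, None, pd.Timestamp("2019-10-01"), "outpatient"))
    bmi = _bmi([("p", 31.0, pd.Timestamp("2019-09-01"))])
    ra = highest_scores(annual_scores(_labs(rows), bmi, birth, "p"))
    assert ra.max_fib4_year == 2017
    assert ra.max_nfs_year == 2019


def test_no_scorable_year_is_unscorable():
    ra = highest_scores(annual_scores(_labs([]), _bmi([]), dt.date(1960, 1, 1), "p"))
    assert ra.max_fib4 is None and ra.max_nfs is None


# ------------------------------------------------------------- categorization

@pytest.mark.parametrize(
    "score, kind, age, expected",
    [
        (3.0, "fib4", 50, "high"),
        (2.67, "fib4", 50, "high"),          # high cutoff inclusive
        (1.5, "fib4", 70, "low"),            # senior low cutoff 2.0
        (1.5, "fib4", 50, "indeterminate"),
        (1.29, "fib4", 50, "low"),
        (1.3, "fib4", 50, "indeterminate"),  # low cutoff exclusive
        (0.676, "nfs", 50, "indeterminate"), # NFS high cutoff strict
        (0.68, "nfs", 50, "high"),
        (-2.0, "nfs", 40, "low"),
        (-2.0, "nfs", 80, "low"),
        (0.0, "nfs", 70, "low"),             # senior low cutoff 0.12
        (0.0, "nfs", 50, "indeterminate"),
    ],
)
def test_age_based_cutoffs(score, kind, age, expected):
    assert categorize_score(score, kind, age, CUT) == expected


@pytest.mark.parametrize(
    "fib4_cat, nfs_cat, expected",
    [
        ("low", "low", "low"),
        ("indeterminate", "indeterminate", "indeterminate"),
        ("high", "high", "high"),
        ("indeterminate", "high", "high"),      # NFS-high bumps one level
        ("low", "high", "indeterminate"),
        ("low", "missing", "low"),
        ("indeterminate", "missing", "indeterminate"),
        ("high", "missing", "high"),
        ("indeterminate", "low", "indeterminate"),  # other discordance: FIB-4
        ("high", "low", "high"),
        ("high", "indeterminate", "high"),
        ("low", "indeterminate", "low"),
        ("missing", "high", "high"),
    ],
)
def test_discordance_resolution_rule(fib4_cat, nfs_cat, expected):
    assert resolve_discordance(fib4_cat, nfs_cat) == expected


def test_both_missing_raises():
    with pytest.raises(ValueError):
        resolve_discordance("missing", "missing")


@given(
    fib4_cat=st.sampled_from(RISK_LEVELS + ("missing",)),
    nfs_cat=st.sampled_from(RISK_LEVELS + ("missing",)),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_one_bump_property(fib4_cat, nfs_cat):
    """final >= FIB-4 category and final <= FIB-4 category + one level."""
    if fib4_cat == "missing":
        return
    final = resolve_discordance(fib4_cat, nfs_cat)
    i_f, i_final = RISK_LEVELS.index(fib4_cat), RISK_LEVELS.index(final)
    assert i_f <= i_final <= i_f + 1


# -------------------------------------------------- cohort-level assignments

def _brute_force_assignment(labs, bmi_obs, birth_date, cutoffs):
    """Independent per-patient recomputation enumerating all labs."""
    best = {"fib4": None, "nfs": None}
    for year in STUDY_YEARS:
        comp = {}
        for analyte in ("AST", "ALT", "platelet", "albumin"):
            cands = [
                (r["collection_date"], r["value"]) for _, r in labs.iterrows()
                if r["analyte"] == analyte and r["setting"] == "outpatient"
                and pd.Timestamp(r["collection_date"]).year == year
            ]
            if cands:
                comp[analyte] = max(cands)[1]
        bc = [
            (r["observation_date"], r["bmi_value"]) for _, r in bmi_obs.iterrows()
            if pd.Timestamp(r["observation_date"]).year == year
        ]
        if bc:
            comp["bmi"] = max(bc)[1]
        age = year - birth_date.year
        if all(k in comp for k in ("AST", "ALT", "platelet")) and comp["ALT"] > 0:
            f = age * comp["AST"] / (comp["platelet"] * math.sqrt(comp["ALT"]))
            if best["fib4"] is None or f > best["fib4"][0]:
                best["fib4"] = (f, age)
            if "albumin" in comp and "bmi" in comp:
                nfs = (-1.675 + 0.037 * age + 0.094 * comp["bmi"] + 1.13
                       + 0.99 * comp["AST"] / comp["ALT"]
                       - 0.013 * comp["platelet"] - 0.66 * comp["albumin"])
                if best["nfs"] is None or nfs > best["nfs"][0]:
                    best["nfs"] = (nfs, age)
    cats = {}
    for kind in ("fib4", "nfs"):
        if best[kind] is None:
            cats[kind] = "missing"
            continue
        score, age = best[kind]
        senior = age >= 65
        if kind == "fib4":
            if score >= 2.67:
                cats[kind] = "high"
            elif score < (2.0 if senior else 1.3):
                cats[kind] = "low"
            else:
                cats[kind] = "indeterminate"
        else:
            if score > 0.676:
                cats[kind] = "high"
            elif score < (0.12 if senior else -1.455):
                cats[kind] = "low"
            else:
                cats[kind] = "indeterminate"
    table = {
        ("low", "high"): "indeterminate",
        ("indeterminate", "high"): "high",
    }
    f, n = cats["fib4"], cats["nfs"]
    if f == "missing" and n == "missing":
        final = "unscorable"
    elif n == "missing" or n == f:
        final = f
    else:
        final = table.get((f, n), f)
    return cats["fib4"], cats["nfs"], final


def test_assignments_agree_with_brute_force_oracle(small_extract):
    """Vectorized assignment equals brute-force per-patient enumeration."""
    extract, _, _ = small_extract
    cohort, _, _ = build_cohort(extract)
    assignments, _ = assign_risk_groups(extract, cohort)
    sub = assignments.sample(n=60, random_state=0)
    labs_by = dict(tuple(extract.labs.groupby("patient_id")))
    bmi_by = dict(tuple(extract.bmi.groupby("patient_id")))
    birth = extract.patients.set_index("patient_id")["birth_date"]
    for row in sub.itertuples(index=False):
        f, n, final = _brute_force_assignment(
            labs_by.get(row.patient_id, extract.labs.iloc[0:0]),
            bmi_by.get(row.patient_id, extract.bmi.iloc[0:0]),
            birth[row.patient_id], CUT,
        )
        assert (row.fib4_category, row.nfs_category, row.final_group) == (f, n, final)


def test_crosstab_partitions_scored_cohort(small_extract):
    extract, _, _ = small_extract
    cohort, _, _ = build_cohort(extract)
    assignments, crosstab = assign_risk_groups(extract, cohort)
    n_scored = int((assignments["final_group"] != "unscorable").sum())
    assert int(crosstab.loc["total", "total"]) == n_scored
    inner = crosstab.drop(index="total", columns="total")
    assert int(inner.to_numpy().sum()) == n_scored
    assert n_scored + int(
        (assignments["final_group"] == "unscorable").sum()
    ) == len(cohort)


def test_assignments_match_generator_truth(small_extract):
    extract, truth, _ = small_extract
    cohort, _, _ = build_cohort(extract)
    assignments, _ = assign_risk_groups(extract, cohort)
    t = truth.patients.set_index("patient_id")
    a = assignments.set_index("patient_id")
    joined = a.join(t[["final_group", "max_fib4", "max_nfs"]], rsuffix="_t")
    assert (joined["final_group"] == joined["final_group_t"]).all()
    got = joined["max_fib4"].astype(float).fillna(-1)
    want = joined["max_fib4_t"].astype(float).fillna(-1)
    assert np.allclose(got, want)
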