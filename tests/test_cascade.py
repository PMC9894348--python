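import datetime as dt

import numpy as np
import pandas as pd
import pytest

from casefinder.cascade_metrics import (
    STAGES,
    CascadeOrderError,
    PerformanceTable,
    StagingRecord,
    cascade_ledger,
    classify_fibrosis_outcome,
    performance_metrics,
    sample_for_validation,
    select_target_group,
)

ANCHOR = dt.date(2020, 7, 1)


def _patients(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "birth_date", "sex", "race_ethnicity",
                 "insurance", "vital_status", "in_system"],
    )


def _assignments(rows):
    return pd.DataFrame(rows, columns=["patient_id", "final_group",
                                       "fib4_category", "nfs_category"])


def _mk_patient(pid, age, vital="alive", in_system=True):
    birth = pd.Timestamp(dt.date(ANCHOR.year - age, ANCHOR.month, ANCHOR.day))
    return (pid, birth, "female", "White", "public", vital, in_system)


class TestTargetSelection:
    def test_age_74_included_75_excluded(self):
        patients = _patients([_mk_patient("a", 74), _mk_patient("b", 75)])
        assignments = _assignments([("a", "high", "high", "high"),
                                    ("b", "high", "high", "high")])
        target, tally = select_target_group(assignments, patients, ANCHOR)
        assert list(target["patient_id"]) == ["a"]
        assert tally["age_excluded"] == 1

    def test_deceased_and_departed_tallied(self):
        patients = _patients([
            _mk_patient("a", 60),
            _mk_patient("b", 60, vital="deceased"),
            _mk_patient("c", 60, in_system=False),
        ])
        assignments = _assignments([(p, "high", "high", "high") for p in "abc"])
        target, tally = select_target_group(assignments, patients, ANCHOR)
        assert list(target["patient_id"]) == ["a"]
        assert tally["dead_or_departed"] == 2

    def test_non_high_risk_never_targeted(self):
        patients = _patients([_mk_patient("a", 60)])
        assignments = _assignments([("a", "indeterminate", "indeterminate", "low")])
        target, tally = select_target_group(assignments, patients, ANCHOR)
        assert target.empty and tally["high_risk"] == 0

    def test_planted_611_339_8_yields_264(self):
        """611 high-risk with 339 at or above the age limit and 8 dead or
        departed among the rest leaves a target group of 264."""
        rows, assigns = [], []
        for i in range(611):
            pid = f"t{i:04d}"
            if i < 339:
                rows.append(_mk_patient(pid, 80))
            elif i < 339 + 5:
                rows.append(_mk_patient(pid, 60, vital="deceased"))
            elif i < 339 + 8:
                rows.append(_mk_patient(pid, 60, in_system=False))
            else:
                rows.append(_mk_patient(pid, 60))
            assigns.append((pid, "high", "high", "high"))
        target, tally = select_target_group(
            _assignments(assigns), _patients(rows), ANCHOR
        )
        assert tally == {"high_risk": 611, "age_excluded": 339,
                         "dead_or_departed": 8, "target": 264}
        assert len(target) == 264


class TestFibrosisClassification:
    def test_lsm_threshold_is_strict(self):
        rec = StagingRecord("p", modality="TE", lsm_kpa=8.0)
        assert classify_fibrosis_outcome(rec).stage_class == "F0_2"
        rec.lsm_kpa = 8.1
        assert classify_fibrosis_outcome(rec).stage_class == "F3_4"

    @pytest.mark.parametrize("modality", ["MRE", "biopsy"])
    @pytest.mark.parametrize("stage, expected",
                             [(2, "F0_2"), (3, "F3_4"), (4, "F3_4")])
    def test_stage_based_modalities(self, modality, stage, expected):
        rec = StagingRecord("p", modality=modality, fibrosis_stage=stage)
        assert classify_fibrosis_outcome(rec).stage_class == expected

    def test_radiological_cirrhosis_is_advanced(self):
        rec = StagingRecord("p", radiological_cirrhosis=True)
        out = classify_fibrosis_outcome(rec)
        assert out.stage_class == "F3_4" and out.basis == "radiological_cirrhosis"

    def test_clinical_assertion_accepted(self):
        rec = StagingRecord("p", modality="clinical", asserted_f3_4=True)
        assert classify_fibrosis_outcome(rec).stage_class == "F3_4"

    def test_absent_modality_is_unstaged(self):
        assert classify_fibrosis_outcome(StagingRecord("p")).stage_class == "unstaged"


def _prefix_events(funnel_counts):
    """Events where the first k_i patients reach stage i."""
    rows = []
    for stage, count in zip(STAGES, funnel_counts):
        for i in range(count):
            rows.append((f"p{i:04d}", stage, None, None))
    return pd.DataFrame(rows, columns=["patient_id", "stage", "stage_detail",
                                       "lsm_kpa"])


class TestLedger:
    def test_planted_funnel_counts_and_proportions(self):
        counts = [264, 149, 118, 118, 90, 78, 69, 25]
        events = _prefix_events(counts)
        targets = [f"p{i:04d}" for i in range(264)]
        ledger = cascade_ledger(events, targets)
        assert list(ledger["count"]) == counts
        pct = dict(zip(ledger["stage"], ledger["pct_of_previous"]))
        assert pct["referred"] == 56
        assert pct["triage_accepted"] == 79
        assert pct["visit_completed"] == 76
        assert pct["nafld_diagnosed"] == 87
        assert pct["staging_completed"] == 88
        assert pct["advanced_fibrosis"] == 36

    def test_empty_event_set_gives_zero_ledger(self):
        events = _prefix_events([0] * 8)
        ledger = cascade_ledger(events, ["p0000"])
        assert (ledger["count"] == 0).all()

    def test_stage_skip_raises_naming_patient(self):
        events = pd.DataFrame(
            [("px", "messaged", None, None),
             ("px", "visit_completed", None, None)],
            columns=["patient_id", "stage", "stage_detail", "lsm_kpa"],
        )
        with pytest.raises(CascadeOrderError, match="px"):
            cascade_ledger(events, ["px"])

    def test_counts_monotone_for_random_valid_funnels(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(1, 120))
            counts = [n]
            for _ in STAGES[1:]:
                counts.append(int(rng.integers(0, counts[-1] + 1)))
            ledger = cascade_ledger(
                _prefix_events(counts), [f"p{i:04d}" for i in range(n)]
            )
            c = list(ledger["count"])
            assert all(a >= b for a, b in zip(c, c[1:]))


class TestPerformance:
    def test_identities_hold_before_rounding(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 60, size=4))
            t = PerformanceTable(tp=tp, fp=fp, tn=tn, fn=fn)
            assert t.sensitivity == pytest.approx(100 * tp / (tp + fn), abs=0.051)
            assert t.specificity == pytest.approx(100 * tn / (tn + fp), abs=0.051)
            assert t.ppv == pytest.approx(100 * tp / (tp + fp), abs=0.051)
            assert t.npv == pytest.approx(100 * tn / (tn + fn), abs=0.051)

    def test_label_swap_swaps_sens_spec_and_ppv_npv(self):
        t = PerformanceTable(tp=15, fp=18, tn=26, fn=10)
        swapped = PerformanceTable(tp=t.tn, fp=t.fn, tn=t.tp, fn=t.fp)
        assert (swapped.sensitivity, swapped.specificity) == (
            t.specificity, t.sensitivity
        )
        assert (swapped.ppv, swapped.npv) == (t.npv, t.ppv)

    def test_zero_denominator_reports_undefined(self):
        t = PerformanceTable(tp=0, fp=0, tn=5, fn=5)
        assert t.ppv is None and t.sensitivity == 0.0

    def test_tabulation_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        cats = ["low", "indeterminate", "high", "missing"]
        n = 200
        assignments = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "fib4_category": rng.choice(cats, size=n),
            "nfs_category": rng.choice(cats, size=n),
        })
        outcomes = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "stage_class": rng.choice(["F3_4", "F0_2", "unstaged"], size=n),
        })
        for rule in ("fib4_high", "nfs_high", "both_high"):
            t = performance_metrics(assignments, outcomes, rule)
            tp = fp = tn = fn = 0
            for i in range(n):
                sc = outcomes["stage_class"][i]
                if sc == "unstaged":
                    continue
                f = assignments["fib4_category"][i] == "high"
                g = assignments["nfs_category"][i] == "high"
                called = {"fib4_high": f, "nfs_high": g, "both_high": f and g}[rule]
                if called and sc == "F3_4":
                    tp += 1
                elif called:
                    fp += 1
                elif sc == "F3_4":
                    fn += 1
                else:
                    tn += 1
            assert (t.tp, t.fp, t.tn, t.fn) == (tp, fp, tn, fn)


class TestValidationSample:
    def test_ten_percent_of_611_is_61(self):
        ids = [f"p{i}" for i in range(611)]
        assert len(sample_for_validation(ids, 0.10, seed=1)) == 61

    def test_seed_reproducibility(self):
        ids = [f"p{i}" for i in range(100)]
        assert sample_for_validation(ids, 0.1, seed=9) == \
            sample_for_validation(ids, 0.1, seed=9)

    def test_fraction_one_returns_whole_list(self):
        ids = ["a", "b", "c"]
        assert sorted(sample_for_validation(ids, 1.0, seed=0)) == ids

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            sample_for_validation(["a"], 0.0)
        with pytest.raises(ValueError):
            sample_for_validation(["a"], 1.5)
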