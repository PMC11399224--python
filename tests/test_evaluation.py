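"""Discharge screening, diagnostic accuracy and incidence comparison."""

import numpy as np
import pytest
from scipy import stats

from ppisentinel.engine import (
    Alert,
    AlertCategory,
    EngineConfig,
    TriagePolicy,
    run_surveillance,
)
from ppisentinel.evaluation import (
    IncidentCategory,
    compare_incidence,
    diagnostic_performance,
    discharge_screen,
    discharge_snapshot_time,
)
from ppisentinel.model import DomainError

from conftest import build_cohort, day


# ---------------------------------------------------------------------------
# discharge screening
# ---------------------------------------------------------------------------


def test_screen_dapt_without_ppi_is_missing(kb, thresholds):
    ds = build_cohort(
        [
            {
                "case_id": "C1",
                "rxs": [
                    {"drug_id": "aspirin", "daily_dose": 100},
                    {"drug_id": "clopidogrel", "daily_dose": 75},
                ],
            }
        ]
    )
    incident = discharge_screen(ds, kb, thresholds, "C1")
    assert incident.category is IncidentCategory.MISSING
    assert incident.alert_nos == (9,)


def test_screen_lone_once_daily_ppi_is_inappropriate(kb, thresholds):
    ds = build_cohort(
        [{"case_id": "C1", "rxs": [{"drug_id": "pantoprazole",
                                    "daily_dose": 40}]}]
    )
    incident = discharge_screen(ds, kb, thresholds, "C1")
    assert incident.category is IncidentCategory.INAPPROPRIATE
    assert incident.alert_nos == (12,)


def test_screen_covered_risk_is_none(kb, thresholds):
    ds = build_cohort(
        [
            {
                "case_id": "C1",
                "rxs": [
                    {"drug_id": "pantoprazole", "daily_dose": 40},
                    {"drug_id": "ibuprofen", "daily_dose": 1200},
                ],
            }
        ]
    )
    assert discharge_screen(ds, kb, thresholds, "C1").category is (
        IncidentCategory.NONE
    )


def test_screen_requires_discharged_case(kb, thresholds):
    ds = build_cohort([{"case_id": "C1"}])
    ds.cases["C1"].discharge = None
    with pytest.raises(DomainError):
        discharge_screen(ds, kb, thresholds, "C1")


def test_snapshot_is_last_tick_strictly_before_discharge():
    ds = build_cohort(
        [{"case_id": "C1", "admission": day(0), "discharge": day(0, 49.5)}]
    )
    case = ds.cases["C1"]
    assert discharge_snapshot_time(case) == day(0, 49)
    # exact grid boundary: strictly before
    ds2 = build_cohort(
        [{"case_id": "C1", "admission": day(0), "discharge": day(0, 48)}]
    )
    assert discharge_snapshot_time(ds2.cases["C1"]) == day(0, 47)


def test_screen_agrees_with_online_engine_on_stable_exposures(kb, thresholds):
    """A case holds an open missing alert at discharge iff the snapshot
    classifies it MISSING, when exposures span the discharge."""
    specs = [
        {"case_id": "C1", "age": 70,
         "rxs": [{"drug_id": "ibuprofen", "daily_dose": 1200}]},
        {"case_id": "C2", "age": 70,
         "rxs": [{"drug_id": "ibuprofen", "daily_dose": 1200},
                 {"drug_id": "pantoprazole", "daily_dose": 40}]},
        {"case_id": "C3", "age": 50,
         "rxs": [{"drug_id": "sertraline", "daily_dose": 50}]},
    ]
    ds = build_cohort(specs)
    log = run_surveillance(
        ds, kb, EngineConfig(triage=TriagePolicy(seed=0, delay_hours=10**6))
    )
    open_missing_at_discharge = {
        a.case_id
        for a in log
        if a.category is AlertCategory.MISSING_PPI
        and a.status_changed_at >= ds.cases[a.case_id].discharge
    }
    for spec in specs:
        cid = spec["case_id"]
        screened = discharge_screen(ds, kb, thresholds, cid).category
        assert (screened is IncidentCategory.MISSING) == (
            cid in open_missing_at_discharge
        )


# ---------------------------------------------------------------------------
# diagnostic performance
# ---------------------------------------------------------------------------


def _alert_for(case_id, category):
    no = 12 if category is AlertCategory.INAPPROPRIATE_PPI else 9
    return Alert(
        alert_id=f"{case_id}-{no}", case_id=case_id, alert_no=no,
        category=category, raised_at=day(1), trigger_profile={},
        trigger_ppi="NONE",
    )


def test_confusion_counts_on_hand_built_fixture():
    """20 labelled cases, 12 tp / 1 fp / 5 tn / 2 fn for MISSING."""
    reference = {}
    log = []
    for i in range(12):  # true positives
        reference[f"TP{i}"] = IncidentCategory.MISSING
        log.append(_alert_for(f"TP{i}", AlertCategory.MISSING_PPI))
    for i in range(2):  # false negatives
        reference[f"FN{i}"] = IncidentCategory.MISSING
    reference["FP0"] = IncidentCategory.NONE  # false positive
    log.append(_alert_for("FP0", AlertCategory.MISSING_PPI))
    for i in range(5):  # true negatives
        reference[f"TN{i}"] = IncidentCategory.NONE
    perf = diagnostic_performance(log, reference)[IncidentCategory.MISSING]
    assert (perf.counts.tp, perf.counts.fp, perf.counts.tn, perf.counts.fn) == (
        12, 1, 5, 2,
    )
    assert perf.sensitivity == pytest.approx(12 / 14)
    assert perf.specificity == pytest.approx(5 / 6)
    assert perf.counts.total == len(reference)


def test_case_set_mismatch_is_an_error():
    log = [_alert_for("GHOST", AlertCategory.MISSING_PPI)]
    with pytest.raises(DomainError):
        diagnostic_performance(log, {"C1": IncidentCategory.NONE})


def test_undefined_denominators_reported_as_none():
    perf = diagnostic_performance([], {"C1": IncidentCategory.NONE})
    assert perf[IncidentCategory.MISSING].sensitivity is None
    assert perf[IncidentCategory.MISSING].specificity == 1.0


def test_performance_matches_brute_force_on_random_fixtures():
    """Randomised cross-check against an independent confusion count."""
    rng = np.random.default_rng(2024)
    categories = [IncidentCategory.MISSING, IncidentCategory.INAPPROPRIATE,
                  IncidentCategory.NONE]
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        ref = {
            f"C{i}": categories[int(rng.integers(0, 3))] for i in range(n)
        }
        log = []
        for i in range(n):
            if rng.random() < 0.4:
                log.append(_alert_for(f"C{i}", AlertCategory.MISSING_PPI))
            if rng.random() < 0.4:
                log.append(_alert_for(f"C{i}", AlertCategory.INAPPROPRIATE_PPI))
        perf = diagnostic_performance(log, ref)
        for category, alert_cat in (
            (IncidentCategory.MISSING, AlertCategory.MISSING_PPI),
            (IncidentCategory.INAPPROPRIATE, AlertCategory.INAPPROPRIATE_PPI),
        ):
            flagged = {a.case_id for a in log if a.category is alert_cat}
            tp = sum(1 for c, k in ref.items() if k is category and c in flagged)
            fp = sum(1 for c, k in ref.items() if k is not category and c in flagged)
            fn = sum(1 for c, k in ref.items() if k is category and c not in flagged)
            tn = n - tp - fp - fn
            counts = perf[category].counts
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# incidence comparison
# ---------------------------------------------------------------------------


def test_identical_rates_give_zero_effect():
    cmp = compare_incidence(50, 1000, 50, 1000)
    assert cmp.relative_reduction == pytest.approx(0.0)
    assert cmp.chi2_statistic == 0.0
    assert cmp.p_value == 1.0


def test_chi_square_matches_textbook_formula():
    """Cross-check the Pearson statistic against the explicit 2x2 formula."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n1, n2 = int(rng.integers(50, 5000)), int(rng.integers(50, 5000))
        a, b = int(rng.integers(1, n1 // 2)), int(rng.integers(1, n2 // 2))
        cmp = compare_incidence(a, n1, b, n2)
        if cmp.chi2_statistic == 0.0:
            continue
        table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        chi2 = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
        assert cmp.chi2_statistic == pytest.approx(chi2, rel=1e-9)
        assert cmp.p_value == pytest.approx(p, rel=1e-9)


def test_swapping_periods_negates_reduction_keeps_p():
    fwd = compare_incidence(67, 5178, 24, 5072)
    rev = compare_incidence(24, 5072, 67, 5178)
    assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)
    # sign flips; magnitudes differ because the base rate changes
    assert fwd.relative_reduction > 0 > rev.relative_reduction


def test_input_validation():
    with pytest.raises(DomainError):
        compare_incidence(5, 0, 1, 10)
    with pytest.raises(DomainError):
        compare_incidence(11, 10, 1, 10)
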