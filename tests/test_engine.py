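"""Risk profiling, alert predicates, suppression, surveillance lifecycle."""

from datetime import timedelta

import pytest

from ppisentinel.engine import (
    AlertCategory,
    AlertStatus,
    EngineConfig,
    PPIStatus,
    RiskProfile,
    TriageDecision,
    TriagePolicy,
    evaluate_case,
    on_demand_exposure,
    ppi_status,
    read_alert_log,
    risk_profile,
    run_surveillance,
    suppress,
    triage_summary,
    write_alert_log,
    Alert,
    InterventionOutcome,
)

from conftest import build_cohort, day


# ---------------------------------------------------------------------------
# risk_profile
# ---------------------------------------------------------------------------


def test_risk_profile_nsaid_plus_antiplatelet(kb, thresholds):
    ds = build_cohort(
        [
            {
                "case_id": "C1",
                "age": 50,
                "rxs": [
                    {"drug_id": "ibuprofen", "daily_dose": 1200},
                    {"drug_id": "clopidogrel", "daily_dose": 75},
                ],
            }
        ]
    )
    p = risk_profile(ds, kb, thresholds, "C1", day(1))
    assert p.nsaid and p.antiplatelet_non_aspirin
    assert not p.dapt
    assert p.factor_count == 2


def test_risk_profile_age_only(kb, thresholds):
    ds = build_cohort([{"case_id": "C1", "age": 70}])
    p = risk_profile(ds, kb, thresholds, "C1", day(1))
    assert p.factors_present() == {"age_ge65"}
    assert p.factor_count == 1


def test_risk_profile_thrombocytopenia_uses_latest_value(kb, thresholds):
    ds = build_cohort(
        [{"case_id": "C1", "age": 40, "labs": [(29, day(1)), (80, day(3))]}]
    )
    assert risk_profile(ds, kb, thresholds, "C1", day(2)).thrombocytes_lt30
    assert not risk_profile(ds, kb, thresholds, "C1", day(4)).thrombocytes_lt30


def test_risk_profile_dapt_counts_distinct_agents(kb, thresholds):
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
    p = risk_profile(ds, kb, thresholds, "C1", day(1))
    assert p.dapt and p.n_antiplatelet_agents == 2
    assert p.factor_count == 1  # antiplatelet therapy is one factor


def test_prophylactic_anticoagulation_is_not_a_factor(kb, thresholds):
    ds = build_cohort(
        [{"case_id": "C1", "rxs": [{"drug_id": "enoxaparin", "daily_dose": 40}]}]
    )
    assert not risk_profile(ds, kb, thresholds, "C1", day(1)).therapeutic_ac


# ---------------------------------------------------------------------------
# on-demand windowing
# ---------------------------------------------------------------------------


def _on_demand_cohort(times):
    return build_cohort(
        [
            {
                "case_id": "C1",
                "discharge": day(10),
                "rxs": [{"drug_id": "M01AE01", "daily_dose": 400,
                         "schedule": "on_demand"}],
                "admins": [(0, t) for t in times],
            }
        ]
    )


def test_on_demand_seven_doses_in_window_counts(thresholds):
    times = [day(4, h) for h in range(0, 42, 6)]  # 7 doses over 36 h
    ds = _on_demand_cohort(times)
    rx = ds.prescriptions["R1"]
    assert on_demand_exposure(ds, thresholds, rx, day(5, 12)) is True


def test_on_demand_six_doses_do_not_count(thresholds):
    times = [day(4, h) for h in range(0, 36, 6)]  # 6 doses
    ds = _on_demand_cohort(times)
    rx = ds.prescriptions["R1"]
    assert on_demand_exposure(ds, thresholds, rx, day(6)) is False


def test_on_demand_old_doses_fall_out_of_window(thresholds):
    # 7 administrations but 2 are older than 48 h at query time
    times = [day(0, 1), day(0, 5)] + [day(3, h) for h in range(0, 30, 6)]
    ds = _on_demand_cohort(times)
    rx = ds.prescriptions["R1"]
    assert on_demand_exposure(ds, thresholds, rx, day(4, 6)) is False


def test_on_demand_nsaid_gates_risk_profile(kb, thresholds):
    times = [day(0, 12 + h) for h in range(0, 42, 6)]
    ds = _on_demand_cohort(times)
    assert risk_profile(ds, kb, thresholds, "C1", day(2)).nsaid
    assert not risk_profile(ds, kb, thresholds, "C1", day(8)).nsaid
    # compatibility flag: open prescription counts unconditionally
    assert risk_profile(
        ds, kb, thresholds, "C1", day(8), replicate_bug_on_demand=True
    ).nsaid


# ---------------------------------------------------------------------------
# PPI status
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rx_overrides, expected",
    [
        ({}, PPIStatus.ORAL_ONCE_DAILY),
        ({"frequency_per_day": 2}, PPIStatus.ORAL_TWICE_DAILY),
        ({"route": "iv"}, PPIStatus.INTRAVENOUS),
    ],
)
def test_ppi_status_modes(kb, rx_overrides, expected):
    rx = {"drug_id": "pantoprazole", "daily_dose": 40, **rx_overrides}
    ds = build_cohort([{"case_id": "C1", "rxs": [rx]}])
    assert ppi_status(ds, kb, "C1", day(1)) is expected


def test_ppi_status_none_without_active_ppi(kb):
    ds = build_cohort(
        [{"case_id": "C1", "rxs": [{"drug_id": "ibuprofen", "daily_dose": 600}]}]
    )
    assert ppi_status(ds, kb, "C1", day(1)) is PPIStatus.NONE


# ---------------------------------------------------------------------------
# predicates and suppression
# ---------------------------------------------------------------------------


def test_nsaid_antiplatelet_and_anticoagulation_candidates():
    p = RiskProfile(nsaid=True, antiplatelet_non_aspirin=True,
                    therapeutic_ac=True)
    assert evaluate_case(p, PPIStatus.NONE) == [1, 2]


def test_dapt_only_fires_alert_9():
    p = RiskProfile(low_dose_aspirin=True, antiplatelet_non_aspirin=True)
    assert evaluate_case(p, PPIStatus.NONE) == [9]


def test_inappropriate_ppi_ignores_age():
    p = RiskProfile(age_ge65=True)
    assert evaluate_case(p, PPIStatus.ORAL_ONCE_DAILY) == [12]


def test_twice_daily_and_iv_ppi_are_appropriate():
    p = RiskProfile()
    assert evaluate_case(p, PPIStatus.ORAL_TWICE_DAILY) == []
    assert evaluate_case(p, PPIStatus.INTRAVENOUS) == []


def test_missing_alerts_require_absent_ppi():
    p = RiskProfile(nsaid=True, age_ge65=True)
    assert evaluate_case(p, PPIStatus.NONE) == [5]
    assert evaluate_case(p, PPIStatus.ORAL_ONCE_DAILY) == []


def test_alert_7_8_need_a_factor_beyond_their_named_triggers():
    base = dict(therapeutic_ac=True, low_dose_aspirin=True,
                antiplatelet_non_aspirin=True, n_antiplatelet_agents=2)
    assert 7 not in evaluate_case(RiskProfile(**base), PPIStatus.NONE)
    assert 7 in evaluate_case(
        RiskProfile(**base, ssri=True), PPIStatus.NONE
    )


def test_no_factors_nothing_fires():
    assert evaluate_case(RiskProfile(), PPIStatus.NONE) == []


@pytest.mark.parametrize(
    "candidates, kept",
    [([1, 2], [1]), ([4, 5, 11], [4]), ([12], [12]), ([], [])],
)
def test_suppress_keeps_lowest_missing_alert(candidates, kept):
    assert suppress(candidates) == kept


# ---------------------------------------------------------------------------
# surveillance loop
# ---------------------------------------------------------------------------


def _risk_case(stop_clopidogrel=None, start_ppi=None):
    """NSAID + clopidogrel case; optional exposure changes mid-stay."""
    rxs = [
        {"drug_id": "ibuprofen", "daily_dose": 1200},
        {"drug_id": "clopidogrel", "daily_dose": 75,
         **({"end": stop_clopidogrel} if stop_clopidogrel else {})},
    ]
    if start_ppi:
        rxs.append({"drug_id": "pantoprazole", "daily_dose": 40,
                    "start": start_ppi})
    return build_cohort(
        [{"case_id": "C1", "age": 50, "discharge": day(5), "rxs": rxs}]
    )


def _engine(seed=0, **kwargs):
    # hands-off triage: alerts stay pending so lifecycle tests observe
    # raising and auto-termination in isolation
    return EngineConfig(
        triage=TriagePolicy(seed=seed, delay_hours=10**6), **kwargs
    )


def test_alert_auto_terminates_when_trigger_clears(kb):
    ds = _risk_case(stop_clopidogrel=day(3))
    log = run_surveillance(ds, kb, _engine())
    (alert,) = [a for a in log if a.alert_no == 1]
    assert alert.status is AlertStatus.RESOLVED
    assert day(3) <= alert.status_changed_at <= day(3, 1)


def test_persistent_trigger_raises_exactly_one_alert(kb):
    ds = _risk_case()
    log = run_surveillance(ds, kb, _engine())
    assert len([a for a in log if a.alert_no == 1]) == 1


def test_empty_cohort_gives_empty_log(kb):
    ds = build_cohort([])
    assert run_surveillance(ds, kb, _engine()) == []


def test_new_ppi_resolves_missing_alert_at_next_tick(kb):
    ds = _risk_case(start_ppi=day(2))
    log = run_surveillance(ds, kb, _engine())
    (alert,) = [a for a in log if a.alert_no == 1]
    assert alert.status is AlertStatus.RESOLVED
    assert alert.status_changed_at <= day(2, 1)
    # the PPI is justified by the active risk factors: no alert 12
    assert not any(a.alert_no == 12 for a in log)


def test_lower_numbered_alert_displaces_open_higher_one(kb):
    # DAPT from admission fires 9; adding an NSAID later fires 1, which
    # must retire the open alert 9: at most one live missing-PPI alert.
    ds = build_cohort(
        [
            {
                "case_id": "C1",
                "age": 50,
                "discharge": day(6),
                "rxs": [
                    {"drug_id": "aspirin", "daily_dose": 100},
                    {"drug_id": "clopidogrel", "daily_dose": 75},
                    {"drug_id": "ibuprofen", "daily_dose": 1200,
                     "start": day(3)},
                ],
            }
        ]
    )
    log = run_surveillance(ds, kb, _engine())
    nines = [a for a in log if a.alert_no == 9]
    ones = [a for a in log if a.alert_no == 1]
    assert len(nines) == 1 and len(ones) == 1
    assert nines[0].status is AlertStatus.RESOLVED
    assert nines[0].status_changed_at <= ones[0].raised_at


def test_discharge_resolves_everything(kb):
    ds = _risk_case()
    log = run_surveillance(ds, kb, _engine())
    assert all(
        a.status in (AlertStatus.RESOLVED, AlertStatus.NOT_RELEVANT)
        for a in log
    )


def test_surveillance_is_deterministic(kb):
    ds = build_cohort(
        [
            {"case_id": f"C{i}", "age": 70 + i, "discharge": day(4),
             "rxs": [{"drug_id": "ibuprofen", "daily_dose": 600}]}
            for i in range(5)
        ]
    )
    cfg = EngineConfig(triage=TriagePolicy(seed=42, default_p_intervention=0.5))
    a = [x.to_record() for x in run_surveillance(ds, kb, cfg)]
    b = [x.to_record() for x in run_surveillance(ds, kb, cfg)]
    assert a == b


def test_at_most_one_live_missing_alert_per_case(kb):
    # many overlapping factors starting at staggered times
    ds = build_cohort(
        [
            {
                "case_id": "C1",
                "age": 70,
                "discharge": day(8),
                "rxs": [
                    {"drug_id": "ibuprofen", "daily_dose": 1200, "start": day(1)},
                    {"drug_id": "clopidogrel", "daily_dose": 75, "start": day(2)},
                    {"drug_id": "rivaroxaban", "daily_dose": 20, "start": day(3)},
                    {"drug_id": "sertraline", "daily_dose": 50, "start": day(4)},
                ],
            }
        ]
    )
    log = run_surveillance(ds, kb, _engine())
    # no two missing-PPI alerts may be open simultaneously
    spans = [
        (a.raised_at, a.status_changed_at or day(8))
        for a in log
        if a.category is AlertCategory.MISSING_PPI
    ]
    for i, (s1, e1) in enumerate(spans):
        for s2, e2 in spans[i + 1:]:
            assert e1 <= s2 or e2 <= s1


# ---------------------------------------------------------------------------
# triage accounting
# ---------------------------------------------------------------------------


def _alert(no, triage=None, outcome=None, case="C1"):
    a = Alert(
        alert_id=f"{case}-{no}", case_id=case, alert_no=no,
        category=(AlertCategory.INAPPROPRIATE_PPI if no == 12
                  else AlertCategory.MISSING_PPI),
        raised_at=day(0), trigger_profile={}, trigger_ppi="NONE",
    )
    a.triage = triage
    a.intervention_outcome = outcome
    return a


def test_acceptance_rate_from_intervention_counts():
    # 81 intervention messages of which 59 accepted -> 72.8%, i.e. 73%
    log = [
        _alert(1, TriageDecision.INTERVENTION,
               InterventionOutcome.ACCEPTED if i < 59
               else InterventionOutcome.NOT_ACCEPTED, case=f"C{i}")
        for i in range(81)
    ]
    summary = triage_summary(log)
    rate = summary.by_category[AlertCategory.MISSING_PPI.value].acceptance_rate
    assert rate == pytest.approx(59 / 81)
    assert round(rate * 100) == 73


def test_acceptance_rate_undefined_without_interventions():
    log = [_alert(9), _alert(12, TriageDecision.NOT_RELEVANT)]
    summary = triage_summary(log)
    assert summary.overall.acceptance_rate is None
    assert summary.overall.problem_resolved == 1
    assert summary.overall.not_relevant == 1


def test_triage_tally_mixed_outcomes():
    log = (
        [_alert(9, TriageDecision.INTERVENTION, InterventionOutcome.ACCEPTED,
                case=f"A{i}") for i in range(5)]
        + [_alert(9, TriageDecision.INTERVENTION,
                  InterventionOutcome.NOT_ACCEPTED, case=f"B{i}")
           for i in range(4)]
        + [_alert(9, TriageDecision.INTERVENTION, InterventionOutcome.UNKNOWN,
                  case="U0")]
    )
    summary = triage_summary(log)
    assert summary.overall.interventions == 10
    assert summary.overall.accepted == 5
    assert summary.overall.unknown == 1
    assert summary.overall.acceptance_rate == pytest.approx(0.5)
    assert summary.by_alert_no == {9: 10}


def test_alert_log_round_trip(kb, tmp_path):
    ds = _risk_case(stop_clopidogrel=day(3))
    log = run_surveillance(ds, kb, _engine())
    path = tmp_path / "alerts.jsonl"
    write_alert_log(log, path)
    loaded = read_alert_log(path)
    assert [a.to_record() for a in loaded] == [a.to_record() for a in log]


def test_illegal_status_transition_rejected():
    a = _alert(9)
    a.transition(AlertStatus.RESOLVED, day(1))
    with pytest.raises(ValueError):
        a.transition(AlertStatus.INTERVENTION, day(2))
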