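"""The PPI surveillance rule engine.

Twelve alert definitions screen each in-hospital case against its current
risk-factor profile and PPI exposure:

* alerts 1-11 ("missing PPI") fire when a gastrointestinal-bleeding risk
  constellation is present and **no** PPI is prescribed;
* alert 12 ("inappropriate PPI") fires when a once-daily oral PPI is
  prescribed with no drug-related risk factor (age >= 65 alone does not
  justify a PPI and is excluded from that check). Intravenous and
  twice-daily PPI prescriptions are treated as appropriate by convention:
  those modes imply an active therapeutic indication.

The countable risk-factor set (used for the ">= 4 risk factors" alert, the
"and risk factor" qualifiers and the inappropriate-PPI check) is: NSAID,
COX-2 inhibitor, antiplatelet therapy (one factor regardless of agent
count), therapeutic anticoagulation, SSRI, age >= 65 years, thrombocytes
< 30 G/L. Corticosteroids >= 10 mg prednisone-equivalent appear only in
the explicitly named trigger combinations (alerts 3 and 10).

Lower-numbered alerts suppress higher-numbered ones so each case carries at
most one open missing-PPI alert. The hourly surveillance loop raises,
deduplicates, triages (seeded stochastic pharmacist stand-in) and
auto-terminates alerts whose trigger conditions have cleared.

Pro re nata (on-demand) NSAID prescriptions count as exposure only when
administered at least ``on_demand_min_doses`` times (default 7, i.e. "more
than six") within the trailing 48-hour window. The
``replicate_bug_on_demand`` compatibility flag instead counts any open
on-demand NSAID prescription unconditionally, which reproduces a known
failure mode in which rarely-used on-demand NSAIDs mask the
inappropriate-PPI alert; it exists so that its effect on sensitivity can be
demonstrated, and is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .knowledge import (
    BaseClass,
    DrugClassKB,
    Qualifier,
    RiskThresholds,
    classify_drug,
    effective_classes,
)
from .model import (
    CohortDataset,
    Prescription,
    active_prescriptions,
    age_at,
    latest_lab,
)

__all__ = [
    "AlertCategory",
    "PPIStatus",
    "RiskProfile",
    "AlertDefinition",
    "ALERT_DEFINITIONS",
    "Alert",
    "AlertStatus",
    "TriageDecision",
    "InterventionOutcome",
    "TriagePolicy",
    "EngineConfig",
    "FOOTNOTE_B_FACTORS",
    "risk_profile",
    "on_demand_exposure",
    "ppi_status",
    "evaluate_case",
    "suppress",
    "run_surveillance",
    "triage_summary",
    "TriageSummary",
    "write_alert_log",
    "read_alert_log",
]

THROMBOCYTES = "thrombocytes"

#: countable risk factors; "antiplatelet_therapy" is one factor no matter
#: how many antiplatelet agents are active.
FOOTNOTE_B_FACTORS = (
    "nsaid",
    "cox2",
    "antiplatelet_therapy",
    "therapeutic_ac",
    "ssri",
    "age_ge65",
    "thrombocytes_lt30",
)


class AlertCategory(str, Enum):
    MISSING_PPI = "MISSING_PPI"
    INAPPROPRIATE_PPI = "INAPPROPRIATE_PPI"


class PPIStatus(str, Enum):
    NONE = "NONE"
    ORAL_ONCE_DAILY = "ORAL_ONCE_DAILY"
    ORAL_TWICE_DAILY = "ORAL_TWICE_DAILY"
    INTRAVENOUS = "INTRAVENOUS"


@dataclass(frozen=True)
class RiskProfile:
    """Risk-factor flags of one case at one time point.

    ``n_antiplatelet_agents`` counts distinct concurrently active
    antiplatelet drugs (aspirin at any dose counts as one agent) and
    drives the DAPT derivation. When constructed by hand without it, the
    count is inferred from the two antiplatelet flags.
    """

    nsaid: bool = False
    cox2: bool = False
    low_dose_aspirin: bool = False
    antiplatelet_non_aspirin: bool = False
    therapeutic_ac: bool = False
    corticosteroid_ge10: bool = False
    ssri: bool = False
    age_ge65: bool = False
    thrombocytes_lt30: bool = False
    n_antiplatelet_agents: int = -1  # -1: infer from flags

    def __post_init__(self):
        if self.n_antiplatelet_agents < 0:
            inferred = int(self.low_dose_aspirin) + int(self.antiplatelet_non_aspirin)
            object.__setattr__(self, "n_antiplatelet_agents", inferred)

    @property
    def antiplatelet_therapy(self) -> bool:
        return self.n_antiplatelet_agents >= 1

    @property
    def dapt(self) -> bool:
        """Dual antiplatelet therapy: >= 2 concurrent antiplatelet agents."""
        return self.n_antiplatelet_agents >= 2

    @property
    def factor_count(self) -> int:
        return sum(1 for f in FOOTNOTE_B_FACTORS if getattr(self, f))

    def factors_present(self) -> frozenset[str]:
        return frozenset(f for f in FOOTNOTE_B_FACTORS if getattr(self, f))

    def flags_dict(self) -> dict:
        return {
            "nsaid": self.nsaid,
            "cox2": self.cox2,
            "low_dose_aspirin": self.low_dose_aspirin,
            "antiplatelet_non_aspirin": self.antiplatelet_non_aspirin,
            "therapeutic_ac": self.therapeutic_ac,
            "corticosteroid_ge10": self.corticosteroid_ge10,
            "ssri": self.ssri,
            "age_ge65": self.age_ge65,
            "thrombocytes_lt30": self.thrombocytes_lt30,
            "n_antiplatelet_agents": self.n_antiplatelet_agents,
            "dapt": self.dapt,
            "factor_count": self.factor_count,
        }


def _extra_factor(profile: RiskProfile, consumed: frozenset[str]) -> bool:
    """Any countable factor not already consumed by an alert's named triggers."""
    return any(f for f in profile.factors_present() if f not in consumed)


@dataclass(frozen=True)
class AlertDefinition:
    alert_no: int
    category: AlertCategory
    trigger_text: str
    predicate: Callable[[RiskProfile, PPIStatus, RiskThresholds], bool]


def _d(no, cat, text, pred) -> AlertDefinition:
    return AlertDefinition(no, cat, text, pred)


_AC_AP = frozenset({"therapeutic_ac", "antiplatelet_therapy"})

ALERT_DEFINITIONS: tuple[AlertDefinition, ...] = (
    _d(1, AlertCategory.MISSING_PPI, "NSAID and antiplatelet therapy",
       lambda p, s, th: p.nsaid and p.antiplatelet_therapy),
    _d(2, AlertCategory.MISSING_PPI, "NSAID and therapeutic anticoagulation",
       lambda p, s, th: p.nsaid and p.therapeutic_ac),
    _d(3, AlertCategory.MISSING_PPI,
       "NSAID and corticosteroid >= 10 mg prednisone equivalent",
       lambda p, s, th: p.nsaid and p.corticosteroid_ge10),
    _d(4, AlertCategory.MISSING_PPI,
       "NSAID and drug associated with gastrointestinal bleeding (SSRI)",
       lambda p, s, th: p.nsaid and p.ssri),
    _d(5, AlertCategory.MISSING_PPI, "NSAID and age >= 65 years",
       lambda p, s, th: p.nsaid and p.age_ge65),
    _d(6, AlertCategory.MISSING_PPI, "NSAID and thrombocytes < 30 G/L",
       lambda p, s, th: p.nsaid and p.thrombocytes_lt30),
    _d(7, AlertCategory.MISSING_PPI,
       "Therapeutic anticoagulation + DAPT and risk factor",
       lambda p, s, th: p.therapeutic_ac and p.dapt and _extra_factor(p, _AC_AP)),
    _d(8, AlertCategory.MISSING_PPI,
       "Therapeutic anticoagulation + low dose aspirin and risk factor",
       lambda p, s, th: p.therapeutic_ac and p.low_dose_aspirin
       and _extra_factor(p, _AC_AP)),
    _d(9, AlertCategory.MISSING_PPI, "Dual antiplatelet therapy (DAPT)",
       lambda p, s, th: p.dapt),
    _d(10, AlertCategory.MISSING_PPI,
       "Low dose aspirin + corticosteroid >= 10 mg prednisone equivalent "
       "and age >= 65 years",
       lambda p, s, th: p.low_dose_aspirin and p.corticosteroid_ge10
       and p.age_ge65),
    _d(11, AlertCategory.MISSING_PPI, ">= 4 risk factors present",
       lambda p, s, th: p.factor_count >= th.multi_factor_min),
    _d(12, AlertCategory.INAPPROPRIATE_PPI,
       "PPI without any risk factors (excluding age >= 65 years)",
       lambda p, s, th: s is PPIStatus.ORAL_ONCE_DAILY
       and not (p.factors_present() - {"age_ge65"})),
)

_DEF_BY_NO = {d.alert_no: d for d in ALERT_DEFINITIONS}


def alert_category(alert_no: int) -> AlertCategory:
    return _DEF_BY_NO[alert_no].category


# ---------------------------------------------------------------------------
# profile computation
# ---------------------------------------------------------------------------


def on_demand_exposure(
    ds: CohortDataset,
    thresholds: RiskThresholds,
    rx: Prescription,
    t: datetime,
) -> bool:
    """Does an on-demand prescription count as exposure at ``t``?

    True iff the number of recorded administrations in the half-open
    window ``(t - on_demand_window, t]`` reaches ``on_demand_min_doses``.
    """
    window_start = t - timedelta(hours=thresholds.on_demand_window_hours)
    times = ds.admins_by_rx.get(rx.rx_id, [])
    n = sum(1 for g in times if window_start < g <= t)
    return n >= thresholds.on_demand_min_doses


def _counts_as_exposure(
    ds: CohortDataset,
    thresholds: RiskThresholds,
    kb: DrugClassKB,
    rx: Prescription,
    t: datetime,
    replicate_bug_on_demand: bool,
) -> bool:
    """On-demand gating: only on-demand NSAIDs are subject to the dose count."""
    if rx.schedule != "on_demand":
        return True
    if classify_drug(kb, rx.drug_id) is not BaseClass.NSAID:
        return True
    if replicate_bug_on_demand:
        # compatibility mode: any open on-demand NSAID counts, regardless
        # of how often it was actually taken
        return True
    return on_demand_exposure(ds, thresholds, rx, t)


def risk_profile(
    ds: CohortDataset,
    kb: DrugClassKB,
    thresholds: RiskThresholds,
    case_id: str,
    t: datetime,
    replicate_bug_on_demand: bool = False,
) -> RiskProfile:
    """Risk-factor flags of ``case_id`` at time ``t``.

    Derived from active prescriptions (with on-demand gating), patient age
    and the latest thrombocyte value at or before ``t``. A missing lab
    means the factor is absent.
    """
    flags = {
        "nsaid": False,
        "cox2": False,
        "low_dose_aspirin": False,
        "antiplatelet_non_aspirin": False,
        "therapeutic_ac": False,
        "corticosteroid_ge10": False,
        "ssri": False,
    }
    ap_agents: set[str] = set()
    for rx in active_prescriptions(ds, case_id, t):
        if not _counts_as_exposure(ds, thresholds, kb, rx, t,
                                   replicate_bug_on_demand):
            continue
        quals = effective_classes(kb, thresholds, rx.drug_id, rx.daily_dose,
                                  rx.route)
        if Qualifier.NSAID in quals:
            flags["nsaid"] = True
        if Qualifier.COX2 in quals:
            flags["cox2"] = True
        if Qualifier.LOW_DOSE_ASPIRIN in quals:
            flags["low_dose_aspirin"] = True
            ap_agents.add("aspirin")
        if Qualifier.ANTIPLATELET in quals:
            if classify_drug(kb, rx.drug_id) is BaseClass.ASPIRIN:
                ap_agents.add("aspirin")  # full-dose aspirin: one agent
            else:
                flags["antiplatelet_non_aspirin"] = True
                ap_agents.add(rx.drug_id)
        if Qualifier.THERAPEUTIC_AC in quals:
            flags["therapeutic_ac"] = True
        if Qualifier.CORTICOSTEROID_GE10 in quals:
            flags["corticosteroid_ge10"] = True
        if Qualifier.SSRI in quals:
            flags["ssri"] = True
    patient = ds.patient_of(case_id)
    lab = latest_lab(ds, case_id, THROMBOCYTES, t)
    return RiskProfile(
        **flags,
        age_ge65=age_at(patient, t) >= thresholds.age_min,
        thrombocytes_lt30=lab is not None and lab.value < thresholds.thrombocyte_max,
        n_antiplatelet_agents=len(ap_agents),
    )


def ppi_status(
    ds: CohortDataset, kb: DrugClassKB, case_id: str, t: datetime
) -> PPIStatus:
    """PPI exposure mode at ``t``: iv > twice-daily oral > once-daily > none."""
    best = PPIStatus.NONE
    for rx in active_prescriptions(ds, case_id, t):
        if classify_drug(kb, rx.drug_id) is not BaseClass.PPI:
            continue
        if rx.route == "iv":
            return PPIStatus.INTRAVENOUS
        if rx.frequency_per_day >= 2:
            best = PPIStatus.ORAL_TWICE_DAILY
        elif best is PPIStatus.NONE:
            best = PPIStatus.ORAL_ONCE_DAILY
    return best


def evaluate_case(
    profile: RiskProfile,
    ppi: PPIStatus,
    thresholds: RiskThresholds | None = None,
) -> list[int]:
    """All alert numbers whose predicate holds, ascending.

    Alerts 1-11 require the absence of any PPI; alert 12 requires a
    once-daily oral PPI and no countable factor besides age.
    """
    th = thresholds or RiskThresholds()
    out = []
    for d in ALERT_DEFINITIONS:
        if d.category is AlertCategory.MISSING_PPI and ppi is not PPIStatus.NONE:
            continue
        if d.predicate(profile, ppi, th):
            out.append(d.alert_no)
    return out


def suppress(candidates: Sequence[int]) -> list[int]:
    """Keep the lowest-numbered missing-PPI candidate; alert 12 passes through.

    Lower-numbered alerts are ranked more clinically relevant and suppress
    higher-numbered ones to avoid duplicate alerts for one constellation.
    """
    missing = [n for n in candidates if n <= 11]
    kept = [min(missing)] if missing else []
    if 12 in candidates:
        kept.append(12)
    return kept


# ---------------------------------------------------------------------------
# alert lifecycle
# ---------------------------------------------------------------------------


class AlertStatus(str, Enum):
    PENDING = "PENDING"
    INTERVENTION = "INTERVENTION"
    NOT_RELEVANT = "NOT_RELEVANT"
    RESOLVED = "RESOLVED"


class TriageDecision(str, Enum):
    INTERVENTION = "INTERVENTION"
    NOT_RELEVANT = "NOT_RELEVANT"


class InterventionOutcome(str, Enum):
    ACCEPTED = "ACCEPTED"
    NOT_ACCEPTED = "NOT_ACCEPTED"
    UNKNOWN = "UNKNOWN"


_ALLOWED_TRANSITIONS = {
    AlertStatus.PENDING: {AlertStatus.INTERVENTION, AlertStatus.NOT_RELEVANT,
                          AlertStatus.RESOLVED},
    AlertStatus.INTERVENTION: {AlertStatus.RESOLVED},
    AlertStatus.NOT_RELEVANT: set(),
    AlertStatus.RESOLVED: set(),
}


@dataclass
class Alert:
    """One raised alert instance with its lifecycle.

    ``triage`` records the pharmacist stand-in's assessment (message sent /
    dismissed / never assessed); ``status`` tracks the live state. An alert
    that received an intervention message and later auto-terminates ends as
    RESOLVED with ``triage`` still INTERVENTION.
    """

    alert_id: str
    case_id: str
    alert_no: int
    category: AlertCategory
    raised_at: datetime
    trigger_profile: dict
    trigger_ppi: str
    status: AlertStatus = AlertStatus.PENDING
    status_changed_at: Optional[datetime] = None
    triage: Optional[TriageDecision] = None
    intervention_outcome: Optional[InterventionOutcome] = None

    def transition(self, new: AlertStatus, at: datetime) -> None:
        if new not in _ALLOWED_TRANSITIONS[self.status]:
            raise ValueError(
                f"illegal alert transition {self.status} -> {new} "
                f"({self.alert_id})"
            )
        self.status = new
        self.status_changed_at = at

    def to_record(self) -> dict:
        return {
            "alert_id": self.alert_id,
            "case_id": self.case_id,
            "alert_no": self.alert_no,
            "category": self.category.value,
            "raised_at": self.raised_at.isoformat(),
            "status": self.status.value,
            "status_changed_at": (
                self.status_changed_at.isoformat()
                if self.status_changed_at else None
            ),
            "triage": self.triage.value if self.triage else None,
            "intervention_outcome": (
                self.intervention_outcome.value
                if self.intervention_outcome else None
            ),
            "trigger_ppi": self.trigger_ppi,
            "trigger_profile": self.trigger_profile,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Alert":
        return cls(
            alert_id=rec["alert_id"],
            case_id=rec["case_id"],
            alert_no=int(rec["alert_no"]),
            category=AlertCategory(rec["category"]),
            raised_at=datetime.fromisoformat(rec["raised_at"]),
            trigger_profile=rec.get("trigger_profile", {}),
            trigger_ppi=rec.get("trigger_ppi", "NONE"),
            status=AlertStatus(rec["status"]),
            status_changed_at=(
                datetime.fromisoformat(rec["status_changed_at"])
                if rec.get("status_changed_at") else None
            ),
            triage=TriageDecision(rec["triage"]) if rec.get("triage") else None,
            intervention_outcome=(
                InterventionOutcome(rec["intervention_outcome"])
                if rec.get("intervention_outcome") else None
            ),
        )


class TriagePolicy(BaseModel):
    """Seeded stochastic stand-in for the pharmacist's relevance assessment.

    After ``delay_hours``, a pending alert becomes an intervention message
    with probability ``p_intervention`` (per alert number, falling back to
    the default), otherwise it is dismissed as not relevant. Interventions
    are accepted / not accepted / unknown with per-category probabilities.
    The degenerate :meth:`always_intervene` mode sends a message for every
    alert immediately, which is the deterministic testing configuration.
    """

    default_p_intervention: float = Field(default=0.5, ge=0, le=1)
    p_intervention_by_alert: dict[int, float] = Field(default_factory=dict)
    p_accept: dict[str, float] = Field(
        default_factory=lambda: {
            AlertCategory.MISSING_PPI.value: 0.73,
            AlertCategory.INAPPROPRIATE_PPI.value: 0.34,
        }
    )
    p_unknown: dict[str, float] = Field(
        default_factory=lambda: {
            AlertCategory.MISSING_PPI.value: 0.10,
            AlertCategory.INAPPROPRIATE_PPI.value: 0.10,
        }
    )
    delay_hours: float = Field(default=4.0, ge=0)
    seed: int = 0

    @field_validator("p_intervention_by_alert", "p_accept", "p_unknown")
    @classmethod
    def _probs(cls, v):
        for key, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {key} out of [0, 1]")
        return v

    @classmethod
    def always_intervene(cls, seed: int = 0) -> "TriagePolicy":
        return cls(default_p_intervention=1.0, delay_hours=0.0, seed=seed)

    def p_for(self, alert_no: int) -> float:
        return self.p_intervention_by_alert.get(
            alert_no, self.default_p_intervention
        )


class EngineConfig(BaseModel):
    """Everything the surveillance loop needs besides the data and the KB."""

    thresholds: RiskThresholds = Field(default_factory=RiskThresholds)
    step_hours: float = Field(default=1.0, gt=0)
    replicate_bug_on_demand: bool = False
    triage: TriagePolicy = Field(default_factory=TriagePolicy)


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, case_index]))


def run_surveillance(
    ds: CohortDataset,
    kb: DrugClassKB,
    config: EngineConfig | None = None,
    t0: Optional[datetime] = None,
    t1: Optional[datetime] = None,
) -> list[Alert]:
    """Replay hourly surveillance over a cohort and return the alert log.

    Ticks lie on the grid ``t0 + k * step``; an event between ticks is
    observed at the next tick, matching the review latency of an hourly
    batch system. Per tick and in-hospital included case: compute the risk
    profile and PPI status, evaluate and suppress candidates, raise new
    alerts (deduplicated against live alerts of the same number), triage
    pending alerts past the policy delay, and auto-terminate alerts whose
    trigger no longer holds (including those displaced by a lower-numbered
    alert). At discharge every remaining live alert is terminated.

    The log is reproducible: identical data, configuration and seed give
    an identical log (triage draws come from a per-case child generator,
    so the outcome of one case never shifts another's draws).
    """
    config = config or EngineConfig()
    th = config.thresholds
    step = timedelta(hours=config.step_hours)

    cases = [
        ds.cases[cid] for cid in ds.included_case_ids()
        if ds.cases[cid].discharge is not None or t1 is not None
    ]
    if not cases:
        return []
    if t0 is None:
        t0 = min(c.admission for c in cases).replace(
            minute=0, second=0, microsecond=0
        )
    if t1 is None:
        t1 = max(c.discharge for c in cases if c.discharge is not None)

    log: list[Alert] = []
    for case_index, case in enumerate(cases):
        rng = _case_rng(config.triage.seed, case_index)
        live: dict[int, Alert] = {}  # alert_no -> non-terminal alert
        n_raised = 0
        # first tick at or after admission on the global grid
        delta = case.admission - t0
        k0 = delta // step
        if t0 + k0 * step < case.admission:
            k0 += 1
        end = case.discharge if case.discharge is not None else t1
        t = t0 + k0 * step
        while t <= t1 and t < end:
            profile = risk_profile(
                ds, kb, th, case.case_id, t, config.replicate_bug_on_demand
            )
            status = ppi_status(ds, kb, case.case_id, t)
            candidates = evaluate_case(profile, status, th)
            kept = set(suppress(candidates))

            # terminate displaced or cleared alerts
            for no in sorted(set(live) - kept):
                alert = live.pop(no)
                if alert.status in (AlertStatus.PENDING, AlertStatus.INTERVENTION):
                    alert.transition(AlertStatus.RESOLVED, t)
                # NOT_RELEVANT alerts simply stop being watched

            # raise new alerts
            for no in sorted(kept - set(live)):
                n_raised += 1
                alert = Alert(
                    alert_id=f"{case.case_id}-a{no}-{n_raised}",
                    case_id=case.case_id,
                    alert_no=no,
                    category=alert_category(no),
                    raised_at=t,
                    trigger_profile=profile.flags_dict(),
                    trigger_ppi=status.value,
                )
                live[no] = alert
                log.append(alert)

            # triage pending alerts past the policy delay
            for no in sorted(live):
                alert = live[no]
                if alert.status is not AlertStatus.PENDING:
                    continue
                age_h = (t - alert.raised_at).total_seconds() / 3600.0
                if age_h < config.triage.delay_hours:
                    continue
                if rng.random() < config.triage.p_for(no):
                    alert.transition(AlertStatus.INTERVENTION, t)
                    alert.triage = TriageDecision.INTERVENTION
                    cat = alert.category.value
                    u = rng.random()
                    p_acc = config.triage.p_accept.get(cat, 0.5)
                    p_unk = config.triage.p_unknown.get(cat, 0.0)
                    if u < p_acc:
                        alert.intervention_outcome = InterventionOutcome.ACCEPTED
                    elif u < p_acc + p_unk:
                        alert.intervention_outcome = InterventionOutcome.UNKNOWN
                    else:
                        alert.intervention_outcome = InterventionOutcome.NOT_ACCEPTED
                else:
                    alert.transition(AlertStatus.NOT_RELEVANT, t)
                    alert.triage = TriageDecision.NOT_RELEVANT
            t += step

        # discharge (or horizon) terminates whatever is still live
        for no in sorted(live):
            alert = live[no]
            if alert.status in (AlertStatus.PENDING, AlertStatus.INTERVENTION):
                alert.transition(AlertStatus.RESOLVED, end)
        live.clear()

    log.sort(key=lambda a: (a.raised_at, a.case_id, a.alert_no))
    return log


# ---------------------------------------------------------------------------
# triage accounting
# ---------------------------------------------------------------------------


@dataclass
class TriageCounts:
    n_alerts: int = 0
    interventions: int = 0
    not_relevant: int = 0
    problem_resolved: int = 0  # auto-terminated without assessment
    accepted: int = 0
    not_accepted: int = 0
    unknown: int = 0

    @property
    def acceptance_rate(self) -> Optional[float]:
        """Accepted interventions over all intervention messages sent."""
        if self.interventions == 0:
            return None
        return self.accepted / self.interventions


@dataclass
class TriageSummary:
    overall: TriageCounts
    by_category: dict[str, TriageCounts]
    by_alert_no: dict[int, int]


def triage_summary(log: Sequence[Alert]) -> TriageSummary:
    """Tally alert dispositions and acceptance rates from a completed log.

    Dispositions are mutually exclusive: an alert counts as *intervention*
    if a message was sent (whatever happened afterwards), as *not relevant*
    if dismissed, and as *problem resolved* if it auto-terminated without
    ever being assessed.
    """
    overall = TriageCounts()
    by_cat = {c.value: TriageCounts() for c in AlertCategory}
    by_no: dict[int, int] = {}
    for alert in log:
        for counts in (overall, by_cat[alert.category.value]):
            counts.n_alerts += 1
            if alert.triage is TriageDecision.INTERVENTION:
                counts.interventions += 1
                if alert.intervention_outcome is InterventionOutcome.ACCEPTED:
                    counts.accepted += 1
                elif alert.intervention_outcome is InterventionOutcome.NOT_ACCEPTED:
                    counts.not_accepted += 1
                elif alert.intervention_outcome is InterventionOutcome.UNKNOWN:
                    counts.unknown += 1
            elif alert.triage is TriageDecision.NOT_RELEVANT:
                counts.not_relevant += 1
            else:
                counts.problem_resolved += 1
        by_no[alert.alert_no] = by_no.get(alert.alert_no, 0) + 1
    return TriageSummary(overall=overall, by_category=by_cat, by_alert_no=by_no)


# ---------------------------------------------------------------------------
# alert-log serialisation (JSON Lines, stable field order)
# ---------------------------------------------------------------------------


def write_alert_log(log: Sequence[Alert], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for alert in log:
            fh.write(json.dumps(alert.to_record()) + "\n")


def read_alert_log(path: str | Path) -> list[Alert]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Alert.from_record(json.loads(line)))
    return out
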