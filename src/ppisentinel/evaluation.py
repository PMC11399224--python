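"""Assessment machinery: discharge screening, diagnostic accuracy, impact.

Three pieces:

* :func:`discharge_screen` re-evaluates the alert predicates once per case
  at the discharge-day snapshot (the last surveillance tick strictly before
  the discharge timestamp) and classifies the case as a missing-PPI
  incident, an inappropriate-PPI incident, or neither. On real data this
  step is a manual record review; here it is the reference standard the
  online engine is compared against.
* :func:`diagnostic_performance` scores an alert log against reference
  labels per category: a case is test-positive for a category if at least
  one alert of that category was raised during its stay. Sensitivity and
  specificity are computed per category, never per individual alert.
* :func:`compare_incidence` is the before/after impact statistic: a 2x2
  chi-square on incident vs non-incident cases across two periods, plus
  the relative reduction of the per-case incidence rate. The Pearson
  statistic without continuity correction is the default; Yates correction
  is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .engine import (
    Alert,
    AlertCategory,
    PPIStatus,
    RiskProfile,
    evaluate_case,
    ppi_status,
    risk_profile,
    suppress,
)
from .knowledge import DrugClassKB, RiskThresholds
from .model import CohortDataset, DomainError, HospitalCase

__all__ = [
    "IncidentCategory",
    "DischargeIncident",
    "ConfusionCounts",
    "DiagnosticPerformance",
    "IncidenceComparison",
    "discharge_snapshot_time",
    "discharge_screen",
    "screen_cohort",
    "diagnostic_performance",
    "compare_incidence",
]


class IncidentCategory(str, Enum):
    MISSING = "MISSING"
    INAPPROPRIATE = "INAPPROPRIATE"
    NONE = "NONE"


_CATEGORY_OF_ALERT_CATEGORY = {
    AlertCategory.MISSING_PPI: IncidentCategory.MISSING,
    AlertCategory.INAPPROPRIATE_PPI: IncidentCategory.INAPPROPRIATE,
}


@dataclass(frozen=True)
class DischargeIncident:
    """Reference-standard classification of one case at discharge."""

    case_id: str
    category: IncidentCategory
    alert_nos: tuple[int, ...]
    profile: RiskProfile
    ppi: PPIStatus
    snapshot_at: datetime


def discharge_snapshot_time(
    case: HospitalCase,
    step_hours: float = 1.0,
    anchor: Optional[datetime] = None,
) -> datetime:
    """Last tick of the ``anchor + k*step`` grid strictly before discharge.

    Defaults to a grid anchored at admission. Clamped to admission for
    stays shorter than one step.
    """
    if case.discharge is None:
        raise DomainError(f"case {case.case_id} is still open")
    anchor = anchor or case.admission
    step = timedelta(hours=step_hours)
    k = (case.discharge - anchor) // step
    t = anchor + k * step
    if t >= case.discharge:
        t -= step
    if t < case.admission:
        t = case.admission
    return t


def discharge_screen(
    ds: CohortDataset,
    kb: DrugClassKB,
    thresholds: RiskThresholds,
    case_id: str,
    step_hours: float = 1.0,
) -> DischargeIncident:
    """Classify one discharged case at the discharge-day snapshot.

    Applies exactly the alert predicates of the online engine (always with
    the corrected on-demand gating) at one time point. A case is MISSING
    when any missing-PPI predicate holds, INAPPROPRIATE when the
    inappropriate-PPI predicate holds, NONE otherwise; the two are
    mutually exclusive because their PPI preconditions conflict.
    """
    case = ds.cases.get(case_id)
    if case is None:
        raise DomainError(f"unknown case {case_id}")
    if case.discharge is None:
        raise DomainError(f"case {case_id} is still open")
    t = discharge_snapshot_time(case, step_hours)
    profile = risk_profile(ds, kb, thresholds, case_id, t)
    status = ppi_status(ds, kb, case_id, t)
    fired = suppress(evaluate_case(profile, status, thresholds))
    if any(n <= 11 for n in fired):
        category = IncidentCategory.MISSING
    elif 12 in fired:
        category = IncidentCategory.INAPPROPRIATE
    else:
        category = IncidentCategory.NONE
    return DischargeIncident(
        case_id=case_id,
        category=category,
        alert_nos=tuple(fired),
        profile=profile,
        ppi=status,
        snapshot_at=t,
    )


def screen_cohort(
    ds: CohortDataset,
    kb: DrugClassKB,
    thresholds: RiskThresholds,
    step_hours: float = 1.0,
) -> list[DischargeIncident]:
    """Discharge screen of every included, discharged case (sorted by id)."""
    return [
        discharge_screen(ds, kb, thresholds, cid, step_hours)
        for cid in ds.included_case_ids()
        if ds.cases[cid].discharge is not None
    ]


# ---------------------------------------------------------------------------
# diagnostic accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity/specificity with explicit n/a for empty denominators."""

    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "DiagnosticPerformance":
        sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
        spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
        return cls(counts=c, sensitivity=sens, specificity=spec)


def _reference_map(
    reference: Sequence[DischargeIncident] | Mapping[str, object] | Iterable,
) -> dict[str, IncidentCategory]:
    if isinstance(reference, Mapping):
        return {
            cid: IncidentCategory(str(cat.value if isinstance(cat, Enum) else cat))
            for cid, cat in reference.items()
        }
    out: dict[str, IncidentCategory] = {}
    for item in reference:
        if isinstance(item, DischargeIncident):
            out[item.case_id] = item.category
        else:  # (case_id, category) pairs or label objects
            cid = getattr(item, "case_id", None)
            cat = getattr(item, "category", None)
            if cid is None:
                cid, cat = item  # type: ignore[misc]
            out[str(cid)] = IncidentCategory(
                str(cat.value if isinstance(cat, Enum) else cat)
            )
    return out


def diagnostic_performance(
    alert_log: Sequence[Alert],
    reference: Sequence[DischargeIncident] | Mapping[str, object] | Iterable,
) -> dict[IncidentCategory, DiagnosticPerformance]:
    """Per-category confusion counts and sensitivity/specificity.

    ``reference`` is one label per case (reference standard); the log must
    not mention cases absent from it. Every reference case with no alert
    of a category is test-negative for that category.
    """
    ref = _reference_map(reference)
    alerted: dict[IncidentCategory, set[str]] = {
        IncidentCategory.MISSING: set(),
        IncidentCategory.INAPPROPRIATE: set(),
    }
    unknown = set()
    for alert in alert_log:
        if alert.case_id not in ref:
            unknown.add(alert.case_id)
            continue
        alerted[_CATEGORY_OF_ALERT_CATEGORY[alert.category]].add(alert.case_id)
    if unknown:
        raise DomainError(
            f"alert log mentions {len(unknown)} case(s) absent from the "
            f"reference set, e.g. {sorted(unknown)[:5]}"
        )
    result = {}
    for category in (IncidentCategory.MISSING, IncidentCategory.INAPPROPRIATE):
        tp = fp = tn = fn = 0
        positives = alerted[category]
        for cid, true_cat in ref.items():
            test_pos = cid in positives
            ref_pos = true_cat is category
            if test_pos and ref_pos:
                tp += 1
            elif test_pos:
                fp += 1
            elif ref_pos:
                fn += 1
            else:
                tn += 1
        result[category] = DiagnosticPerformance.from_counts(
            ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        )
    return result


# ---------------------------------------------------------------------------
# incidence impact
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncidenceComparison:
    """Before/after comparison of per-case incidence rates.

    ``relative_reduction`` is ``(rate_a - rate_b) / rate_a * 100`` in
    percent: positive when period B (with surveillance) has the lower
    rate. Report it rounded to one decimal.
    """

    incidents_a: int
    cases_a: int
    incidents_b: int
    cases_b: int
    rate_a: float
    rate_b: float
    relative_reduction: Optional[float]
    chi2_statistic: float
    p_value: float
    correction_used: bool


def compare_incidence(
    incidents_a: int,
    cases_a: int,
    incidents_b: int,
    cases_b: int,
    correction: bool = False,
) -> IncidenceComparison:
    """2x2 chi-square of incident counts across two observation periods."""
    for label, inc, n in (("a", incidents_a, cases_a), ("b", incidents_b, cases_b)):
        if n <= 0:
            raise DomainError(f"period {label}: number of cases must be positive")
        if not 0 <= inc <= n:
            raise DomainError(
                f"period {label}: incidents must lie in [0, cases]"
            )
    table = [
        [incidents_a, cases_a - incidents_a],
        [incidents_b, cases_b - incidents_b],
    ]
    rate_a = incidents_a / cases_a
    rate_b = incidents_b / cases_b
    if rate_a == rate_b:
        chi2, p = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=correction)
        chi2, p = float(res.statistic), float(res.pvalue)
    reduction = (
        (rate_a - rate_b) / rate_a * 100.0 if rate_a > 0 else None
    )
    return IncidenceComparison(
        incidents_a=incidents_a,
        cases_a=cases_a,
        incidents_b=incidents_b,
        cases_b=cases_b,
        rate_a=rate_a,
        rate_b=rate_b,
        relative_reduction=reduction,
        chi2_statistic=chi2,
        p_value=p,
        correction_used=correction,
    )
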