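"""Longitudinal inpatient data model and plain-CSV readers/writers.

A cohort is five tables — patients, hospital cases, prescriptions, dose
administrations, laboratory results — linked by opaque identifiers. All
timestamps are naive ISO-8601 in one implicit timezone per dataset. Time
intervals are half-open ``[start, end)``: the ``end`` of a stopped
prescription is the first moment it is no longer valid, which avoids
double-counting exposure at switch times.

Inclusion mirrors the surveillance conventions: cases of patients without
consent, or younger than 18 years at admission, are kept in the dataset but
flagged excluded and ignored by the engine and the evaluation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Patient",
    "HospitalCase",
    "Prescription",
    "Administration",
    "LabResult",
    "CohortDataset",
    "CohortLoadError",
    "DomainError",
    "load_cohort",
    "save_cohort",
    "active_prescriptions",
    "age_at",
    "latest_lab",
    "COHORT_FILES",
]

COHORT_FILES = {
    "patients": "patients.csv",
    "cases": "cases.csv",
    "prescriptions": "prescriptions.csv",
    "administrations": "administrations.csv",
    "labs": "labs.csv",
}


class DomainError(ValueError):
    """A query violated a domain precondition (unknown case, t before birth...)."""


class CohortLoadError(ValueError):
    """Raised when cohort files fail validation; carries row-level messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "cohort failed validation:\n" + "\n".join(problems[:50])
        )


class Patient(BaseModel):
    patient_id: str
    birth_date: date
    sex: Literal["M", "F"]
    consent: bool = True


class HospitalCase(BaseModel):
    case_id: str
    patient_id: str
    admission: datetime
    discharge: Optional[datetime] = None
    period_label: Literal["baseline", "intervention"] = "intervention"

    @model_validator(mode="after")
    def _ordered(self):
        if self.discharge is not None and not self.admission < self.discharge:
            raise ValueError(
                f"case {self.case_id}: admission must precede discharge"
            )
        return self


class Prescription(BaseModel):
    rx_id: str
    case_id: str
    drug_id: str
    daily_dose: float = Field(ge=0)
    dose_unit: str = "mg"
    route: Literal["oral", "iv", "other"] = "oral"
    frequency_per_day: int = Field(default=1, ge=1)
    schedule: Literal["regular", "on_demand"] = "regular"
    start: datetime
    end: Optional[datetime] = None

    @model_validator(mode="after")
    def _ordered(self):
        if self.end is not None and not self.start < self.end:
            raise ValueError(f"rx {self.rx_id}: start must precede end")
        return self


class Administration(BaseModel):
    admin_id: str
    rx_id: str
    given_at: datetime


class LabResult(BaseModel):
    case_id: str
    analyte: str
    value: float = Field(ge=0)
    unit: str = "G/L"
    measured_at: datetime


@dataclass
class CohortDataset:
    """Validated in-memory cohort with lookup indexes.

    ``excluded_cases`` maps case_id -> reason for cases outside the
    surveillance population (no consent / minor at admission). Referential
    integrity is guaranteed after :func:`load_cohort` or generator output.
    """

    patients: dict[str, Patient]
    cases: dict[str, HospitalCase]
    prescriptions: dict[str, Prescription]
    administrations: list[Administration]
    labs: list[LabResult]
    provenance: dict = field(default_factory=dict)
    excluded_cases: dict[str, str] = field(default_factory=dict)
    # indexes, built post-init
    rx_by_case: dict[str, list[Prescription]] = field(default_factory=dict)
    admins_by_rx: dict[str, list[datetime]] = field(default_factory=dict)
    labs_by_case: dict[tuple[str, str], list[tuple[datetime, LabResult]]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        self.rebuild_indexes()

    def rebuild_indexes(self) -> None:
        self.rx_by_case = {}
        for rx in self.prescriptions.values():
            self.rx_by_case.setdefault(rx.case_id, []).append(rx)
        for rxs in self.rx_by_case.values():
            rxs.sort(key=lambda r: (r.start, r.rx_id))
        self.admins_by_rx = {}
        for adm in self.administrations:
            self.admins_by_rx.setdefault(adm.rx_id, []).append(adm.given_at)
        for times in self.admins_by_rx.values():
            times.sort()
        self.labs_by_case = {}
        for lab in self.labs:
            key = (lab.case_id, lab.analyte)
            self.labs_by_case.setdefault(key, []).append((lab.measured_at, lab))
        for entries in self.labs_by_case.values():
            entries.sort(key=lambda e: e[0])
        self.excluded_cases = {}
        for case in self.cases.values():
            patient = self.patients[case.patient_id]
            if not patient.consent:
                self.excluded_cases[case.case_id] = "no_consent"
            elif age_at(patient, case.admission) < 18:
                self.excluded_cases[case.case_id] = "minor_at_admission"

    def included_case_ids(self) -> list[str]:
        return sorted(c for c in self.cases if c not in self.excluded_cases)

    def patient_of(self, case_id: str) -> Patient:
        case = self.cases.get(case_id)
        if case is None:
            raise DomainError(f"unknown case {case_id}")
        return self.patients[case.patient_id]


def age_at(patient: Patient, t: datetime | date) -> int:
    """Completed years of age at ``t``; the birthday itself counts as attained."""
    d = t.date() if isinstance(t, datetime) else t
    b = patient.birth_date
    if d < b:
        raise DomainError(f"time {d} precedes birth date of {patient.patient_id}")
    return d.year - b.year - ((d.month, d.day) < (b.month, b.day))


def active_prescriptions(
    ds: CohortDataset, case_id: str, t: datetime
) -> list[Prescription]:
    """Prescriptions of ``case_id`` valid at ``t`` (half-open ``[start, end)``).

    On-demand prescriptions are returned like any other open prescription;
    whether they count as exposure is decided by the rule engine's
    48-hour administration-count gate.
    """
    if case_id not in ds.cases:
        raise DomainError(f"unknown case {case_id}")
    out = []
    for rx in ds.rx_by_case.get(case_id, []):
        if rx.start <= t and (rx.end is None or t < rx.end):
            out.append(rx)
    return out


def latest_lab(
    ds: CohortDataset, case_id: str, analyte: str, t: datetime
) -> Optional[LabResult]:
    """Most recent result of ``analyte`` with ``measured_at <= t``, or None."""
    if case_id not in ds.cases:
        raise DomainError(f"unknown case {case_id}")
    entries = ds.labs_by_case.get((case_id, analyte), [])
    times = [e[0] for e in entries]
    i = bisect.bisect_right(times, t)
    if i == 0:
        return None
    return entries[i - 1][1]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_ts(value: str, problems: list[str], where: str) -> Optional[datetime]:
    if value is None or value == "" or pd.isna(value):
        return None
    try:
        return datetime.fromisoformat(str(value))
    except ValueError:
        problems.append(f"{where}: unparseable timestamp {value!r}")
        return None


def _read_table(path: Path, columns: list[str], problems: list[str]) -> pd.DataFrame:
    if not path.exists():
        problems.append(f"{path.name}: file not found")
        return pd.DataFrame(columns=columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        problems.append(f"{path.name}: missing columns {missing}")
    return df


def load_cohort(path: str | Path, period_label: str | None = None) -> CohortDataset:
    """Load and validate the five cohort CSVs from directory ``path``.

    Rows violating the schema or referential integrity abort the load with
    a :class:`CohortLoadError` naming each offending file and row number
    (1-based, excluding the header). Consent and adult-at-admission
    exclusions are flags on the returned dataset, not errors.
    """
    root = Path(path)
    problems: list[str] = []

    pat_df = _read_table(root / COHORT_FILES["patients"], ["patient_id", "birth_date", "sex", "consent"], problems)
    case_df = _read_table(root / COHORT_FILES["cases"], ["case_id", "patient_id", "admission", "discharge", "period_label"], problems)
    rx_df = _read_table(root / COHORT_FILES["prescriptions"], ["rx_id", "case_id", "drug_id", "daily_dose", "dose_unit", "route", "frequency_per_day", "schedule", "start", "end"], problems)
    adm_df = _read_table(root / COHORT_FILES["administrations"], ["admin_id", "rx_id", "given_at"], problems)
    lab_df = _read_table(root / COHORT_FILES["labs"], ["case_id", "analyte", "value", "unit", "measured_at"], problems)
    if problems:
        raise CohortLoadError(problems)

    patients: dict[str, Patient] = {}
    for i, row in enumerate(pat_df.itertuples(index=False), start=1):
        where = f"patients.csv row {i}"
        if row.patient_id in patients:
            problems.append(f"{where}: duplicate patient_id {row.patient_id}")
            continue
        try:
            patients[row.patient_id] = Patient(
                patient_id=row.patient_id,
                birth_date=date.fromisoformat(row.birth_date),
                sex=row.sex,
                consent=str(row.consent).strip().lower() in ("true", "1", "yes"),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"{where}: {exc}")

    cases: dict[str, HospitalCase] = {}
    for i, row in enumerate(case_df.itertuples(index=False), start=1):
        where = f"cases.csv row {i}"
        if row.case_id in cases:
            problems.append(f"{where}: duplicate case_id {row.case_id}")
            continue
        if row.patient_id not in patients:
            problems.append(f"{where}: unknown patient_id {row.patient_id}")
            continue
        admission = _parse_ts(row.admission, problems, where)
        if admission is None:
            continue
        try:
            cases[row.case_id] = HospitalCase(
                case_id=row.case_id,
                patient_id=row.patient_id,
                admission=admission,
                discharge=_parse_ts(row.discharge, problems, where),
                period_label=row.period_label or "intervention",
            )
        except ValueError as exc:
            problems.append(f"{where}: {exc}")

    prescriptions: dict[str, Prescription] = {}
    for i, row in enumerate(rx_df.itertuples(index=False), start=1):
        where = f"prescriptions.csv row {i}"
        if row.rx_id in prescriptions:
            problems.append(f"{where}: duplicate rx_id {row.rx_id}")
            continue
        if row.case_id not in cases:
            problems.append(f"{where}: unknown case_id {row.case_id}")
            continue
        start = _parse_ts(row.start, problems, where)
        if start is None:
            continue
        try:
            prescriptions[row.rx_id] = Prescription(
                rx_id=row.rx_id,
                case_id=row.case_id,
                drug_id=row.drug_id,
                daily_dose=float(row.daily_dose),
                dose_unit=row.dose_unit or "mg",
                route=row.route or "oral",
                frequency_per_day=int(row.frequency_per_day or 1),
                schedule=row.schedule or "regular",
                start=start,
                end=_parse_ts(row.end, problems, where),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"{where}: {exc}")

    administrations: list[Administration] = []
    seen_admin: set[str] = set()
    for i, row in enumerate(adm_df.itertuples(index=False), start=1):
        where = f"administrations.csv row {i}"
        if row.admin_id in seen_admin:
            problems.append(f"{where}: duplicate admin_id {row.admin_id}")
            continue
        if row.rx_id not in prescriptions:
            problems.append(f"{where}: unknown rx_id {row.rx_id}")
            continue
        given_at = _parse_ts(row.given_at, problems, where)
        if given_at is None:
            continue
        seen_admin.add(row.admin_id)
        administrations.append(
            Administration(admin_id=row.admin_id, rx_id=row.rx_id, given_at=given_at)
        )

    labs: list[LabResult] = []
    for i, row in enumerate(lab_df.itertuples(index=False), start=1):
        where = f"labs.csv row {i}"
        if row.case_id not in cases:
            problems.append(f"{where}: unknown case_id {row.case_id}")
            continue
        measured_at = _parse_ts(row.measured_at, problems, where)
        if measured_at is None:
            continue
        try:
            labs.append(
                LabResult(
                    case_id=row.case_id,
                    analyte=row.analyte,
                    value=float(row.value),
                    unit=row.unit or "G/L",
                    measured_at=measured_at,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"{where}: {exc}")

    if problems:
        raise CohortLoadError(problems)

    ds = CohortDataset(
        patients=patients,
        cases=cases,
        prescriptions=prescriptions,
        administrations=administrations,
        labs=labs,
        provenance={"source": str(root)},
    )
    if period_label is not None:
        for case in ds.cases.values():
            case.period_label = period_label  # type: ignore[assignment]
    return ds


def _fmt_ts(t: Optional[datetime]) -> str:
    return "" if t is None else t.isoformat()


def save_cohort(ds: CohortDataset, out_dir: str | Path) -> None:
    """Write the five cohort CSVs (UTF-8, RFC-4180, empty string = missing)."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "sex": p.sex,
                "consent": str(p.consent).lower(),
            }
            for p in ds.patients.values()
        ],
        columns=["patient_id", "birth_date", "sex", "consent"],
    ).to_csv(root / COHORT_FILES["patients"], index=False)
    pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "patient_id": c.patient_id,
                "admission": _fmt_ts(c.admission),
                "discharge": _fmt_ts(c.discharge),
                "period_label": c.period_label,
            }
            for c in ds.cases.values()
        ],
        columns=["case_id", "patient_id", "admission", "discharge", "period_label"],
    ).to_csv(root / COHORT_FILES["cases"], index=False)
    pd.DataFrame(
        [
            {
                "rx_id": r.rx_id,
                "case_id": r.case_id,
                "drug_id": r.drug_id,
                "daily_dose": r.daily_dose,
                "dose_unit": r.dose_unit,
                "route": r.route,
                "frequency_per_day": r.frequency_per_day,
                "schedule": r.schedule,
                "start": _fmt_ts(r.start),
                "end": _fmt_ts(r.end),
            }
            for r in ds.prescriptions.values()
        ],
        columns=["rx_id", "case_id", "drug_id", "daily_dose", "dose_unit", "route", "frequency_per_day", "schedule", "start", "end"],
    ).to_csv(root / COHORT_FILES["prescriptions"], index=False)
    pd.DataFrame(
        [
            {
                "admin_id": a.admin_id,
                "rx_id": a.rx_id,
                "given_at": _fmt_ts(a.given_at),
            }
            for a in ds.administrations
        ],
        columns=["admin_id", "rx_id", "given_at"],
    ).to_csv(root / COHORT_FILES["administrations"], index=False)
    pd.DataFrame(
        [
            {
                "case_id": l.case_id,
                "analyte": l.analyte,
                "value": l.value,
                "unit": l.unit,
                "measured_at": _fmt_ts(l.measured_at),
            }
            for l in ds.labs
        ],
        columns=["case_id", "analyte", "value", "unit", "measured_at"],
    ).to_csv(root / COHORT_FILES["labs"], index=False)
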