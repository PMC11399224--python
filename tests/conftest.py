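"""Shared fixtures: default KB/thresholds and a tiny-cohort builder."""

from datetime import date, datetime, timedelta

import pytest

from ppisentinel.knowledge import RiskThresholds, default_kb
from ppisentinel.model import (
    Administration,
    CohortDataset,
    HospitalCase,
    LabResult,
    Patient,
    Prescription,
)

T0 = datetime(2021, 7, 1, 8, 0)


def day(n: float, hours: float = 0.0) -> datetime:
    return T0 + timedelta(days=n, hours=hours)


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture(scope="session")
def thresholds():
    return RiskThresholds()


def build_cohort(case_specs: list[dict]) -> CohortDataset:
    """Construct a small in-memory cohort from terse specs.

    Each spec: ``case_id``; optional ``age`` (years at admission),
    ``consent``, ``admission``, ``discharge``, ``period``;
    ``rxs`` is a list of dicts forwarded to :class:`Prescription`
    (rx_id/case_id/start/end defaulted); ``labs`` is a list of
    ``(value, measured_at)`` thrombocyte results; ``admins`` is a list of
    ``(rx_index, given_at)``.
    """
    patients, cases, prescriptions = {}, {}, {}
    administrations, labs = [], []
    n_rx = 0
    n_admin = 0
    for spec in case_specs:
        cid = spec["case_id"]
        pid = f"P{cid}"
        admission = spec.get("admission", day(0))
        discharge = spec.get("discharge", day(5))
        age = spec.get("age", 50)
        birth = admission.date() - timedelta(days=round(age * 365.25) + 40)
        patients[pid] = Patient(
            patient_id=pid,
            birth_date=birth,
            sex=spec.get("sex", "F"),
            consent=spec.get("consent", True),
        )
        cases[cid] = HospitalCase(
            case_id=cid,
            patient_id=pid,
            admission=admission,
            discharge=discharge,
            period_label=spec.get("period", "intervention"),
        )
        case_rx_ids = []
        for rx_spec in spec.get("rxs", []):
            n_rx += 1
            rx_spec = dict(rx_spec)
            rx_spec.setdefault("rx_id", f"R{n_rx}")
            rx_spec.setdefault("case_id", cid)
            rx_spec.setdefault("start", admission)
            rx_spec.setdefault("end", (discharge or day(30)) + timedelta(days=1))
            rx = Prescription(**rx_spec)
            prescriptions[rx.rx_id] = rx
            case_rx_ids.append(rx.rx_id)
        for value, at in spec.get("labs", []):
            labs.append(
                LabResult(
                    case_id=cid, analyte="thrombocytes", value=value,
                    unit="G/L", measured_at=at,
                )
            )
        for rx_index, at in spec.get("admins", []):
            n_admin += 1
            administrations.append(
                Administration(
                    admin_id=f"A{n_admin}",
                    rx_id=case_rx_ids[rx_index],
                    given_at=at,
                )
            )
    return CohortDataset(
        patients=patients,
        cases=cases,
        prescriptions=prescriptions,
        administrations=administrations,
        labs=labs,
    )
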