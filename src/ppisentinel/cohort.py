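"""Seeded synthetic two-period inpatient cohort generator.

The generator emulates a three-month tertiary-care discharge cohort:
age/sex/stay-length distributions, per-factor drug exposure rates, a ~33%
PPI prescription rate and a small consent-refusal fraction, with injected,
labelled incidents of *missing PPI* (a bleeding-risk constellation at
discharge without gastroprotection) and *inappropriate PPI* (a once-daily
oral PPI at discharge without any drug-related risk factor).

Incidents are injected by construction, not rejection sampling: the
generator picks the alert row to realise, then emits the minimal
prescriptions/labs that make exactly that predicate true across the
discharge snapshot. Non-incident cases are built so that no alert
predicate ever holds during the stay: risk constellations that would fire
are covered by a PPI from admission, PPIs without a qualifying risk factor
are emitted as twice-daily (the convention treats those as appropriate and
they stand in for indication-driven prescriptions the data model cannot
express), and remaining background exposures are checked against the
alert truth table before being left uncovered. Ground-truth labels are
therefore exact by construction.

Background exposure probabilities are adjusted for the exposure mass the
injected incidents add, so the realised per-factor case counts stay on the
configured targets. Same seed, same config => byte-identical output.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
import yaml

from . import __version__
from .engine import PPIStatus, RiskProfile, evaluate_case
from .evaluation import IncidentCategory
from .knowledge import (
    BaseClass,
    DrugClassKB,
    RiskThresholds,
    classify_drug,
    default_kb,
    effective_classes,
    Qualifier,
)
from .model import (
    Administration,
    CohortDataset,
    HospitalCase,
    LabResult,
    Patient,
    Prescription,
    age_at,
    save_cohort,
)

__all__ = [
    "CohortConfig",
    "PeriodConfig",
    "GroundTruthLabel",
    "generate_cohort",
    "write_cohort",
    "read_labels",
    "load_cohort_config",
    "preset_config",
    "exposure_margins",
    "FACTOR_NAMES",
]

FACTOR_NAMES = (
    "nsaid",
    "cox2",
    "low_dose_aspirin",
    "antiplatelet_non_aspirin",
    "therapeutic_ac",
    "corticosteroid_ge10",
    "ssri",
    "thrombocytes_lt30",
)

# one concrete product realising each drug factor: (drug_id, daily dose,
# unit, frequency/day)
_FACTOR_RX = {
    "nsaid": ("M01AE01", 1200.0, "mg", 3),           # ibuprofen
    "cox2": ("M01AH05", 90.0, "mg", 1),              # etoricoxib
    "low_dose_aspirin": ("B01AC06", 100.0, "mg", 1),
    "antiplatelet_non_aspirin": ("B01AC04", 75.0, "mg", 1),  # clopidogrel
    "therapeutic_ac": ("B01AF01", 20.0, "mg", 1),    # rivaroxaban
    "corticosteroid_ge10": ("H02AB07", 20.0, "mg", 1),  # prednisone
    "ssri": ("N06AB10", 10.0, "mg", 1),              # escitalopram
}

_PPI_RX = ("A02BC02", 40.0, "mg")  # pantoprazole

# clinically inert background products (classify as OTHER)
_FILLER_DRUGS = (
    ("N02BE01", 3000.0),  # paracetamol
    ("C07AB07", 5.0),     # bisoprolol
    ("C10AA05", 40.0),    # atorvastatin
    ("A10BA02", 2000.0),  # metformin
    ("C09AA05", 5.0),     # ramipril
    ("C03CA01", 40.0),    # furosemide
    ("N05BA06", 1.0),     # lorazepam
    ("A06AD15", 10.0),    # macrogol
    ("N02AA05", 10.0),    # oxycodone
    ("R03AC02", 0.8),     # salbutamol
    ("L04AX03", 15.0),    # methotrexate
    ("H03AA01", 0.1),     # levothyroxine
)

#: drug factors (and forced age) realising each missing-PPI alert row
_ROW_FACTORS: dict[int, frozenset[str]] = {
    1: frozenset({"nsaid", "antiplatelet_non_aspirin"}),
    2: frozenset({"nsaid", "therapeutic_ac"}),
    3: frozenset({"nsaid", "corticosteroid_ge10"}),
    4: frozenset({"nsaid", "ssri"}),
    5: frozenset({"nsaid"}),
    6: frozenset({"nsaid", "thrombocytes_lt30"}),
    7: frozenset({"therapeutic_ac", "low_dose_aspirin",
                  "antiplatelet_non_aspirin"}),
    8: frozenset({"therapeutic_ac", "low_dose_aspirin"}),
    9: frozenset({"low_dose_aspirin", "antiplatelet_non_aspirin"}),
    10: frozenset({"low_dose_aspirin", "corticosteroid_ge10"}),
    11: frozenset({"cox2", "antiplatelet_non_aspirin", "therapeutic_ac",
                   "ssri"}),
}
_ROW_NEEDS_AGE = frozenset({5, 7, 8, 10})


class Band(BaseModel):
    lo: float
    hi: float
    weight: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lo < self.hi:
            raise ValueError("band lo must be < hi")
        return self


class PeriodConfig(BaseModel):
    label: Literal["baseline", "intervention"]
    n_cases: int = Field(ge=1)
    admission_start: date
    admission_end: date
    missing_rate: float = Field(ge=0, le=1)
    inappropriate_rate: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _feasible(self):
        if self.missing_rate + self.inappropriate_rate > 1:
            raise ValueError("incident rates must sum to at most 1")
        if not self.admission_start <= self.admission_end:
            raise ValueError("admission window is empty")
        return self


class CohortConfig(BaseModel):
    """Everything the generator needs; ``seed`` is mandatory."""

    seed: int
    periods: list[PeriodConfig]
    consent_refusal_rate: float = Field(default=0.08, ge=0, le=1)
    sex_female: float = Field(default=0.51, ge=0, le=1)
    age_bands: list[Band]
    stay_bands: list[Band]  # days
    exposure_targets: dict[str, float]  # per-factor case fraction
    ppi_target: float = Field(default=0.33, ge=0, le=1)
    mean_filler_drugs: float = Field(default=9.0, ge=0)
    on_demand_nsaid_rate: float = Field(default=0.3, ge=0, le=1)
    missing_row_weights: dict[int, float]
    normal_tc_lab_rate: float = Field(default=0.4, ge=0, le=1)

    @field_validator("exposure_targets")
    @classmethod
    def _known_factors(cls, v):
        for name, p in v.items():
            if name not in FACTOR_NAMES:
                raise ValueError(f"unknown exposure factor {name!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"exposure target {name} out of [0, 1]")
        return v

    @field_validator("missing_row_weights")
    @classmethod
    def _known_rows(cls, v):
        for no, w in v.items():
            if no not in _ROW_FACTORS:
                raise ValueError(f"unknown missing-PPI alert row {no}")
            if w < 0:
                raise ValueError("row weights must be non-negative")
        if sum(v.values()) <= 0:
            raise ValueError("row weights must not all be zero")
        return v

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode("utf-8")
        ).hexdigest()


@dataclass(frozen=True)
class GroundTruthLabel:
    """Injected reference-standard category of one case at discharge."""

    case_id: str
    category: IncidentCategory
    trigger: str  # which alert row the construction realises, or ""
    indicated_ppi: bool  # PPI emitted as appropriate despite no drug factor


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------


def load_cohort_config(path: str | Path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return CohortConfig(**raw)


def preset_config(
    seed: int = 0,
    scale: float = 1.0,
    periods: Optional[list[str]] = None,
) -> CohortConfig:
    """The packaged two-period preset, optionally scaled down.

    ``scale`` multiplies the per-period case counts (incident rates and
    margins are proportions and stay put); ``periods`` selects a subset by
    label.
    """
    from importlib import resources

    raw = yaml.safe_load(
        resources.files("ppisentinel.data")
        .joinpath("table2_2021.yaml")
        .read_text(encoding="utf-8")
    )
    cfg = CohortConfig(**raw)
    cfg = cfg.model_copy(update={"seed": seed})
    if periods is not None:
        cfg.periods = [p for p in cfg.periods if p.label in periods]
        if not cfg.periods:
            raise ValueError(f"no preset period matches {periods}")
    if scale != 1.0:
        cfg.periods = [
            p.model_copy(update={"n_cases": max(1, round(p.n_cases * scale))})
            for p in cfg.periods
        ]
    return cfg


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------


def _row_probs(weights: dict[int, float]) -> tuple[list[int], np.ndarray]:
    rows = sorted(weights)
    w = np.array([weights[r] for r in rows], dtype=float)
    return rows, w / w.sum()


def _adjusted_background_probs(
    cfg: CohortConfig, period: PeriodConfig
) -> dict[str, float]:
    """Deflate background exposure draws by the injected-incident mass.

    A factor's realised per-case probability is
    ``1 - (1-q)(1-c)`` where ``q`` is the background draw and ``c`` the
    probability that the case is a missing-PPI incident whose alert row
    requires the factor; solving for ``q`` keeps the margin on target.
    """
    rows, probs = _row_probs(cfg.missing_row_weights)
    out = {}
    for name in FACTOR_NAMES:
        target = cfg.exposure_targets.get(name, 0.0)
        c = period.missing_rate * sum(
            p for r, p in zip(rows, probs) if name in _ROW_FACTORS[r]
        )
        q = (target - c) / (1.0 - c) if c < 1 else 0.0
        out[name] = min(max(q, 0.0), 1.0)
    return out


def _p_age_ge65(cfg: CohortConfig) -> float:
    total = sum(b.weight for b in cfg.age_bands)
    return sum(b.weight for b in cfg.age_bands if b.lo >= 65) / total


def _fire_probability(
    q: dict[str, float], p_age: float, thresholds: RiskThresholds
) -> float:
    """Exact probability that an independent background draw fires any
    missing-PPI predicate, by enumeration of all flag combinations."""
    names = list(FACTOR_NAMES)
    p_fire = 0.0
    for bits in itertools.product((False, True), repeat=len(names) + 1):
        flags = dict(zip(names, bits[:-1]))
        age = bits[-1]
        weight = np.prod(
            [q[n] if flags[n] else 1 - q[n] for n in names]
        ) * (p_age if age else 1 - p_age)
        if weight == 0.0:
            continue
        profile = _profile_from_flags(flags, age)
        if any(n <= 11 for n in evaluate_case(profile, PPIStatus.NONE,
                                              thresholds)):
            p_fire += float(weight)
    return p_fire


def _profile_from_flags(flags: dict[str, bool], age_ge65: bool) -> RiskProfile:
    return RiskProfile(
        nsaid=flags.get("nsaid", False),
        cox2=flags.get("cox2", False),
        low_dose_aspirin=flags.get("low_dose_aspirin", False),
        antiplatelet_non_aspirin=flags.get("antiplatelet_non_aspirin", False),
        therapeutic_ac=flags.get("therapeutic_ac", False),
        corticosteroid_ge10=flags.get("corticosteroid_ge10", False),
        ssri=flags.get("ssri", False),
        age_ge65=age_ge65,
        thrombocytes_lt30=flags.get("thrombocytes_lt30", False),
        n_antiplatelet_agents=(
            int(flags.get("low_dose_aspirin", False))
            + int(flags.get("antiplatelet_non_aspirin", False))
        ),
    )


def _adjusted_ppi_prob(
    cfg: CohortConfig, period: PeriodConfig, p_fire: float
) -> float:
    """Background PPI draw so the overall PPI margin lands on target.

    PPI mass comes from inappropriate-PPI incidents, from risk
    constellations that must be covered, and from the residual background
    draw solved for here.
    """
    r_m, r_i = period.missing_rate, period.inappropriate_rate
    none_mass = 1.0 - r_m - r_i
    residual = cfg.ppi_target - r_i - none_mass * p_fire
    denom = none_mass * (1.0 - p_fire)
    if denom <= 0:
        return 0.0
    return min(max(residual / denom, 0.0), 1.0)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _to_minute(t: datetime) -> datetime:
    """EHR timestamps carry minute resolution."""
    return t.replace(second=0, microsecond=0)


def _sample_band(bands: list[Band], rng: np.random.Generator) -> float:
    weights = np.array([b.weight for b in bands], dtype=float)
    weights /= weights.sum()
    i = int(rng.choice(len(bands), p=weights))
    return float(rng.uniform(bands[i].lo, bands[i].hi))


def _birth_date_for(
    admission: datetime, age_years: float, discharge: datetime
) -> date:
    """Birth date realising ``age_years`` whose anniversary avoids the stay.

    Keeping the birthday out of ``[admission - 1 d, discharge + 2 d]``
    makes the completed-years age constant over the whole stay, so every
    generator decision based on age holds at every surveillance tick.
    """
    birth = admission.date() - timedelta(days=round(age_years * 365.25))
    lo = admission.date() - timedelta(days=1)
    hi = discharge.date() + timedelta(days=2)
    for _ in range(3):
        try:
            anniversary = birth.replace(year=lo.year)
        except ValueError:  # Feb 29
            anniversary = birth.replace(year=lo.year, day=28)
        if lo <= anniversary <= hi or (
            anniversary.year < hi.year
            and lo <= anniversary.replace(year=hi.year) <= hi
        ):
            birth -= timedelta(days=45)
            continue
        break
    return birth


class _CaseBuilder:
    """Accumulates the rows of one synthetic case."""

    def __init__(self, ids: "_IdFactory"):
        self.ids = ids
        self.prescriptions: list[Prescription] = []
        self.administrations: list[Administration] = []
        self.labs: list[LabResult] = []

    def add_rx(
        self,
        case_id: str,
        drug_id: str,
        dose: float,
        unit: str,
        freq: int,
        start: datetime,
        end: datetime,
        route: str = "oral",
        schedule: str = "regular",
    ) -> Prescription:
        rx = Prescription(
            rx_id=self.ids.rx(),
            case_id=case_id,
            drug_id=drug_id,
            daily_dose=dose,
            dose_unit=unit,
            route=route,
            frequency_per_day=freq,
            schedule=schedule,
            start=start,
            end=end,
        )
        self.prescriptions.append(rx)
        return rx

    def add_factor_rx(
        self, case_id: str, factor: str, start: datetime, end: datetime
    ) -> None:
        drug_id, dose, unit, freq = _FACTOR_RX[factor]
        self.add_rx(case_id, drug_id, dose, unit, freq, start, end)

    def add_lab(
        self, case_id: str, value: float, at: datetime
    ) -> None:
        self.labs.append(
            LabResult(
                case_id=case_id,
                analyte="thrombocytes",
                value=value,
                unit="G/L",
                measured_at=at,
            )
        )


class _IdFactory:
    def __init__(self):
        self.n_rx = 0
        self.n_admin = 0

    def rx(self) -> str:
        self.n_rx += 1
        return f"R{self.n_rx:07d}"

    def admin(self) -> str:
        self.n_admin += 1
        return f"D{self.n_admin:07d}"


def generate_cohort(
    config: CohortConfig,
    kb: Optional[DrugClassKB] = None,
    thresholds: Optional[RiskThresholds] = None,
) -> tuple[CohortDataset, list[GroundTruthLabel]]:
    """Generate a referentially intact labelled cohort.

    Every injected incident case carries prescriptions/labs that make
    exactly the intended alert predicate true at (and across) the
    discharge snapshot; every non-incident case is constructed so that no
    alert predicate holds at any time during the stay.
    """
    kb = kb or default_kb()
    thresholds = thresholds or RiskThresholds()
    rng = np.random.default_rng(config.seed)
    ids = _IdFactory()

    patients: dict[str, Patient] = {}
    cases: dict[str, HospitalCase] = {}
    prescriptions: dict[str, Prescription] = {}
    administrations: list[Administration] = []
    labs: list[LabResult] = []
    labels: list[GroundTruthLabel] = []

    rows, row_probs = _row_probs(config.missing_row_weights)
    age_hi = max(b.hi for b in config.age_bands)
    p_age = _p_age_ge65(config)

    for period in config.periods:
        q = _adjusted_background_probs(config, period)
        p_fire = _fire_probability(q, p_age, thresholds)
        q_ppi = _adjusted_ppi_prob(config, period, p_fire)
        prefix = "B" if period.label == "baseline" else "I"
        window_days = (period.admission_end - period.admission_start).days

        for i in range(period.n_cases):
            case_id = f"{prefix}{i:05d}"
            patient_id = f"P{case_id}"
            builder = _CaseBuilder(ids)

            # --- demographics and stay -------------------------------------
            adm_day = int(rng.integers(0, window_days + 1))
            admission = datetime.combine(
                period.admission_start + timedelta(days=adm_day),
                datetime.min.time(),
            ) + timedelta(
                hours=int(rng.integers(0, 24)), minutes=int(rng.integers(0, 60))
            )
            stay_days = _sample_band(config.stay_bands, rng)
            discharge = admission + timedelta(
                minutes=round(stay_days * 24 * 60)
            )
            age_years = _sample_band(config.age_bands, rng)
            sex = "F" if rng.random() < config.sex_female else "M"
            consent = rng.random() >= config.consent_refusal_rate

            # --- incident category and background draws --------------------
            u = rng.random()
            if u < period.missing_rate:
                category = IncidentCategory.MISSING
            elif u < period.missing_rate + period.inappropriate_rate:
                category = IncidentCategory.INAPPROPRIATE
            else:
                category = IncidentCategory.NONE
            background = {
                name: bool(rng.random() < q[name]) for name in FACTOR_NAMES
            }

            trigger = ""
            indicated = False
            if category is IncidentCategory.MISSING:
                row = int(rng.choice(rows, p=row_probs))
                if row in _ROW_NEEDS_AGE and age_years < 65.5:
                    age_years = float(rng.uniform(65.5, age_hi))
                trigger = f"alert_{row}"
            birth = _birth_date_for(admission, age_years, discharge)
            patient = Patient(
                patient_id=patient_id, birth_date=birth, sex=sex,
                consent=consent,
            )
            age_ge65 = age_at(patient, admission) >= thresholds.age_min

            span_start = admission
            span_end = discharge + timedelta(days=1)
            mid = _to_minute(admission + (discharge - admission) / 2)
            if mid <= admission:
                mid = admission + timedelta(minutes=1)

            if category is IncidentCategory.MISSING:
                required = _ROW_FACTORS[row]
                late_start = max(admission, discharge - timedelta(hours=48))
                for factor in sorted(required):
                    background.pop(factor, None)
                    if factor == "thrombocytes_lt30":
                        builder.add_lab(
                            case_id, float(rng.uniform(5, 25)), late_start
                        )
                    else:
                        builder.add_factor_rx(
                            case_id, factor, late_start, span_end
                        )
                # background factors float mid-stay and end before the
                # discharge snapshot; no PPI is ever prescribed
                for factor, present in sorted(background.items()):
                    if not present:
                        continue
                    if factor == "thrombocytes_lt30":
                        builder.add_lab(
                            case_id, float(rng.uniform(5, 25)), admission
                        )
                    else:
                        builder.add_factor_rx(case_id, factor, admission, mid)

            elif category is IncidentCategory.INAPPROPRIATE:
                # once-daily oral PPI across discharge; every background
                # factor is covered by the PPI and cleared before the
                # discharge snapshot
                builder.add_rx(
                    case_id, _PPI_RX[0], _PPI_RX[1], _PPI_RX[2], 1,
                    span_start, span_end,
                )
                for factor, present in sorted(background.items()):
                    if not present:
                        continue
                    if factor == "thrombocytes_lt30":
                        builder.add_lab(
                            case_id, float(rng.uniform(5, 25)), admission
                        )
                        builder.add_lab(
                            case_id, float(rng.uniform(150, 350)), mid
                        )
                    else:
                        builder.add_factor_rx(case_id, factor, admission, mid)
                if rng.random() < config.on_demand_nsaid_rate:
                    # sparse pro re nata NSAID: never reaches the 48-h dose
                    # threshold, so it must not mask the alert
                    rx = builder.add_rx(
                        case_id, _FACTOR_RX["nsaid"][0], 400.0, "mg", 1,
                        span_start, span_end, schedule="on_demand",
                    )
                    n_doses = int(rng.integers(1, 4))
                    stay_h = (discharge - admission).total_seconds() / 3600
                    for k in range(n_doses):
                        at = _to_minute(
                            admission + timedelta(
                                hours=float(
                                    rng.uniform(0.5, max(1.0, stay_h - 0.5))
                                )
                            )
                        )
                        builder.administrations.append(
                            Administration(
                                admin_id=ids.admin(), rx_id=rx.rx_id,
                                given_at=min(max(at, admission), discharge),
                            )
                        )

            else:  # NONE
                profile = _profile_from_flags(background, age_ge65)
                fires = any(
                    n <= 11
                    for n in evaluate_case(profile, PPIStatus.NONE, thresholds)
                )
                # a once-daily PPI stays appropriate only while a countable
                # factor (age excluded) is present; corticosteroids appear
                # in named trigger combinations but not in that set
                blocks_alert_12 = bool(
                    profile.factors_present() - {"age_ge65"}
                )
                give_ppi = fires or (rng.random() < q_ppi)
                if give_ppi and (fires or blocks_alert_12):
                    # risk factors covered by a once-daily PPI from admission
                    builder.add_rx(
                        case_id, _PPI_RX[0], _PPI_RX[1], _PPI_RX[2], 1,
                        span_start, span_end,
                    )
                elif give_ppi:
                    # no qualifying factor: emit as twice-daily, the
                    # convention's stand-in for an indicated prescription
                    builder.add_rx(
                        case_id, _PPI_RX[0], _PPI_RX[1] * 2, _PPI_RX[2], 2,
                        span_start, span_end,
                    )
                    indicated = True
                for factor, present in sorted(background.items()):
                    if not present:
                        continue
                    if factor == "thrombocytes_lt30":
                        builder.add_lab(
                            case_id, float(rng.uniform(5, 25)), admission
                        )
                    else:
                        builder.add_factor_rx(
                            case_id, factor, span_start, span_end
                        )

            # routine thrombocyte lab for cases without the low-value factor
            if (
                not background.get("thrombocytes_lt30", False)
                and category is not IncidentCategory.MISSING
                and rng.random() < config.normal_tc_lab_rate
            ):
                builder.add_lab(
                    case_id, float(rng.uniform(150, 350)), admission
                )

            # clinically inert concomitant medication
            n_filler = int(rng.poisson(config.mean_filler_drugs))
            stay = discharge - admission
            for _ in range(n_filler):
                drug_id, dose = _FILLER_DRUGS[
                    int(rng.integers(0, len(_FILLER_DRUGS)))
                ]
                f_start = _to_minute(
                    admission + stay * float(rng.uniform(0, 0.3))
                )
                f_end = _to_minute(f_start + stay * float(rng.uniform(0.2, 0.9)))
                builder.add_rx(
                    case_id, drug_id, dose, "mg", 1, f_start,
                    max(min(f_end, span_end), f_start + timedelta(minutes=1)),
                )

            patients[patient_id] = patient
            cases[case_id] = HospitalCase(
                case_id=case_id,
                patient_id=patient_id,
                admission=admission,
                discharge=discharge,
                period_label=period.label,
            )
            for rx in builder.prescriptions:
                prescriptions[rx.rx_id] = rx
            administrations.extend(builder.administrations)
            labs.extend(builder.labs)
            labels.append(
                GroundTruthLabel(
                    case_id=case_id,
                    category=category,
                    trigger=trigger,
                    indicated_ppi=indicated,
                )
            )

    ds = CohortDataset(
        patients=patients,
        cases=cases,
        prescriptions=prescriptions,
        administrations=administrations,
        labs=labs,
        provenance={
            "generator_seed": config.seed,
            "config_hash": config.config_hash(),
            "kb_version": kb.version,
            "package_version": __version__,
        },
    )
    return ds, labels


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_cohort(
    ds: CohortDataset,
    labels: list[GroundTruthLabel],
    out_dir: str | Path,
) -> None:
    """Emit the five cohort CSVs, labels.csv and a provenance manifest."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    save_cohort(ds, root)
    pd.DataFrame(
        [
            {
                "case_id": lab.case_id,
                "category": lab.category.value,
                "trigger": lab.trigger,
                "indicated_ppi": str(lab.indicated_ppi).lower(),
            }
            for lab in labels
        ],
        columns=["case_id", "category", "trigger", "indicated_ppi"],
    ).to_csv(root / "labels.csv", index=False)
    manifest = dict(ds.provenance)
    manifest["n_cases"] = len(ds.cases)
    manifest["n_prescriptions"] = len(ds.prescriptions)
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_labels(path: str | Path) -> list[GroundTruthLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        GroundTruthLabel(
            case_id=row.case_id,
            category=IncidentCategory(row.category),
            trigger=row.trigger,
            indicated_ppi=str(row.indicated_ppi).lower() == "true",
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# margin measurement (used for calibration checks and reports)
# ---------------------------------------------------------------------------


def exposure_margins(
    ds: CohortDataset,
    kb: Optional[DrugClassKB] = None,
    thresholds: Optional[RiskThresholds] = None,
) -> dict[str, float | int]:
    """Per-factor case counts over included cases, by trigger conventions.

    A case counts as exposed to a factor if any regular prescription
    carries the corresponding qualifier at its prescribed dose; on-demand
    NSAIDs count only if seven administrations ever fall within 48 hours.
    Age is evaluated at admission; thrombocytopenia counts on any value
    below the cut-off during the stay.
    """
    kb = kb or default_kb()
    thresholds = thresholds or RiskThresholds()
    counts = {name: 0 for name in FACTOR_NAMES}
    counts["age_ge65"] = 0
    counts["ppi"] = 0
    included = ds.included_case_ids()
    ages = []
    for cid in included:
        case = ds.cases[cid]
        patient = ds.patients[case.patient_id]
        found: set[str] = set()
        for rx in ds.rx_by_case.get(cid, []):
            base = classify_drug(kb, rx.drug_id)
            if base is BaseClass.PPI:
                found.add("ppi")
                continue
            if rx.schedule == "on_demand" and base is BaseClass.NSAID:
                times = ds.admins_by_rx.get(rx.rx_id, [])
                k = thresholds.on_demand_min_doses
                window = timedelta(hours=thresholds.on_demand_window_hours)
                if any(
                    times[i + k - 1] - times[i] <= window
                    for i in range(len(times) - k + 1)
                ):
                    found.add("nsaid")
                continue
            quals = effective_classes(
                kb, thresholds, rx.drug_id, rx.daily_dose, rx.route
            )
            if Qualifier.NSAID in quals:
                found.add("nsaid")
            if Qualifier.COX2 in quals:
                found.add("cox2")
            if Qualifier.LOW_DOSE_ASPIRIN in quals:
                found.add("low_dose_aspirin")
            if Qualifier.ANTIPLATELET in quals and base is not BaseClass.ASPIRIN:
                found.add("antiplatelet_non_aspirin")
            if Qualifier.THERAPEUTIC_AC in quals:
                found.add("therapeutic_ac")
            if Qualifier.CORTICOSTEROID_GE10 in quals:
                found.add("corticosteroid_ge10")
            if Qualifier.SSRI in quals:
                found.add("ssri")
        entries = ds.labs_by_case.get((cid, "thrombocytes"), [])
        if any(e[1].value < thresholds.thrombocyte_max for e in entries):
            found.add("thrombocytes_lt30")
        if age_at(patient, case.admission) >= thresholds.age_min:
            found.add("age_ge65")
        ages.append(
            (case.admission.date() - patient.birth_date).days / 365.25
        )
        for name in found:
            counts[name] += 1
    out: dict[str, float | int] = dict(counts)
    out["n_cases"] = len(included)
    out["mean_age"] = float(np.mean(ages)) if ages else float("nan")
    return out
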