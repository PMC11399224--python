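"""Drug-class knowledge base with dose-dependent risk qualifiers.

Drug products are identified by ATC codes (exact or prefix, longest match
wins) or by lower-case alias names resolved through an explicit alias table.
Classification happens in two stages:

1. :func:`classify_drug` maps an identifier to a *base class*
   (NSAID, PPI, anticoagulant, ...).
2. :func:`effective_classes` refines the base class with dose-dependent
   qualifiers: aspirin splits into low-dose antiplatelet use versus
   full-dose use, anticoagulants only count when dosed therapeutically,
   and corticosteroids only count at >= 10 mg prednisone equivalent per day.

All cut-offs live in the knowledge-base document and
:class:`RiskThresholds`; nothing is hard-coded, because the clinical
conventions behind them (e.g. which daily dose of a given LMWH counts as
therapeutic anticoagulation) are local consensus, not universal guideline
values.
"""

from __future__ import annotations

import re
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "BaseClass",
    "Qualifier",
    "DrugClassKB",
    "RiskThresholds",
    "KBError",
    "classify_drug",
    "effective_classes",
    "prednisone_equivalent",
    "load_kb",
    "save_kb",
    "default_kb",
]

_ATC_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")


class KBError(ValueError):
    """Raised for malformed identifiers or inconsistent KB configuration."""


class BaseClass(str, Enum):
    """Coarse drug class of a product, independent of dose and route."""

    NSAID = "NSAID"
    COX2 = "COX2"
    ASPIRIN = "ASPIRIN"
    ANTIPLATELET_NON_ASPIRIN = "ANTIPLATELET_NON_ASPIRIN"
    ANTICOAGULANT = "ANTICOAGULANT"
    CORTICOSTEROID = "CORTICOSTEROID"
    SSRI = "SSRI"
    PPI = "PPI"
    OTHER = "OTHER"


class Qualifier(str, Enum):
    """Risk-relevant exposure qualifier after applying dose rules."""

    NSAID = "NSAID"
    COX2 = "COX2"
    LOW_DOSE_ASPIRIN = "LOW_DOSE_ASPIRIN"
    ANTIPLATELET = "ANTIPLATELET"
    THERAPEUTIC_AC = "THERAPEUTIC_AC"
    CORTICOSTEROID_GE10 = "CORTICOSTEROID_GE10"
    SSRI = "SSRI"
    PPI = "PPI"


_RISK_CLASSES = {
    BaseClass.NSAID,
    BaseClass.COX2,
    BaseClass.ASPIRIN,
    BaseClass.ANTIPLATELET_NON_ASPIRIN,
    BaseClass.ANTICOAGULANT,
    BaseClass.CORTICOSTEROID,
    BaseClass.SSRI,
}


class RiskThresholds(BaseModel):
    """Numeric cut-offs used by the alert predicates.

    ``on_demand_min_doses`` = 7 encodes "more than six administrations
    within the 48-hour window" for pro re nata NSAIDs.
    """

    corticosteroid_min_prednisone_eq: float = 10.0  # mg prednisone-eq / day
    age_min: int = 65  # years
    thrombocyte_max: float = 30.0  # G/L (exclusive upper bound)
    multi_factor_min: int = 4
    on_demand_min_doses: int = 7
    on_demand_window_hours: float = 48.0
    min_exposure_hours: float = 0.0  # minimum validity before a rx counts

    @field_validator(
        "corticosteroid_min_prednisone_eq",
        "age_min",
        "thrombocyte_max",
        "multi_factor_min",
        "on_demand_window_hours",
    )
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("threshold must be strictly positive")
        return v

    @field_validator("on_demand_min_doses")
    @classmethod
    def _ge_one(cls, v):
        if v < 1:
            raise ValueError("on_demand_min_doses must be >= 1")
        return v

    @field_validator("min_exposure_hours")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("min_exposure_hours must be >= 0")
        return v


class DrugClassKB(BaseModel):
    """ATC-prefix classification table plus dose-rule parameters.

    ``classes`` maps ATC codes or prefixes to a :class:`BaseClass`;
    lookups take the longest matching prefix. ``aliases`` resolves
    lower-case drug names to ATC codes. ``corticosteroid_potency``
    stores prednisone-equivalence factors (mg prednisone per mg drug);
    ``anticoagulant_thresholds`` stores the minimum daily dose (native
    unit of the product) counted as therapeutic anticoagulation.
    """

    version: str = "unversioned"
    classes: dict[str, BaseClass]
    aliases: dict[str, str] = Field(default_factory=dict)
    corticosteroid_potency: dict[str, float] = Field(default_factory=dict)
    anticoagulant_thresholds: dict[str, float] = Field(default_factory=dict)
    aspirin_low_dose_max: float = 325.0  # mg/day

    @field_validator("classes")
    @classmethod
    def _valid_codes(cls, v: dict[str, BaseClass]):
        for code in v:
            if not _ATC_RE.match(code):
                raise ValueError(f"invalid ATC code or prefix: {code!r}")
        return v

    @field_validator("corticosteroid_potency")
    @classmethod
    def _positive_potency(cls, v: dict[str, float]):
        for code, factor in v.items():
            if factor <= 0:
                raise ValueError(f"potency factor for {code} must be > 0")
        return v

    @field_validator("aspirin_low_dose_max")
    @classmethod
    def _positive_limit(cls, v: float):
        if v <= 0:
            raise ValueError("aspirin_low_dose_max must be > 0")
        return v

    @model_validator(mode="after")
    def _check_consistency(self):
        # PPI membership must be disjoint from every risk-factor class:
        # no risk entry may refine a PPI prefix or vice versa.
        ppi_codes = [c for c, k in self.classes.items() if k is BaseClass.PPI]
        risk_codes = [c for c, k in self.classes.items() if k in _RISK_CLASSES]
        for p in ppi_codes:
            for r in risk_codes:
                if p.startswith(r) or r.startswith(p):
                    raise ValueError(
                        f"PPI entry {p} overlaps risk-class entry {r}"
                    )
        for name, target in self.aliases.items():
            if not _ATC_RE.match(target):
                raise ValueError(f"alias {name!r} maps to invalid code {target!r}")
        return self


def _resolve(kb: DrugClassKB, drug_id: str) -> str:
    """Resolve an alias or ATC identifier to an upper-case ATC code."""
    if not isinstance(drug_id, str) or not drug_id.strip():
        raise KBError(f"malformed drug identifier: {drug_id!r}")
    token = drug_id.strip()
    alias = kb.aliases.get(token.lower())
    if alias is not None:
        return alias
    code = token.upper()
    if not _ATC_RE.match(code):
        raise KBError(f"malformed drug identifier: {drug_id!r}")
    return code


def _longest_prefix(table: Mapping[str, object], code: str):
    best_len = -1
    best = None
    for prefix, value in table.items():
        if code.startswith(prefix) and len(prefix) > best_len:
            best_len = len(prefix)
            best = value
    return best


def classify_drug(kb: DrugClassKB, drug_id: str) -> BaseClass:
    """Base class of ``drug_id`` by longest ATC-prefix match.

    Returns :attr:`BaseClass.OTHER` when no entry matches.
    """
    code = _resolve(kb, drug_id)
    found = _longest_prefix(kb.classes, code)
    return found if found is not None else BaseClass.OTHER


def prednisone_equivalent(kb: DrugClassKB, drug_id: str, daily_dose: float) -> float:
    """Daily dose expressed as mg prednisone-equivalent per day.

    Linear in dose: ``daily_dose`` (mg of the product) times the agent's
    potency factor. Raises :class:`KBError` for non-corticosteroids and
    for corticosteroids missing a potency entry.
    """
    code = _resolve(kb, drug_id)
    if classify_drug(kb, code) is not BaseClass.CORTICOSTEROID:
        raise KBError(f"{drug_id} is not a corticosteroid in this KB")
    factor = _longest_prefix(kb.corticosteroid_potency, code)
    if factor is None:
        raise KBError(f"corticosteroid {drug_id} has no potency factor configured")
    return daily_dose * float(factor)


def effective_classes(
    kb: DrugClassKB,
    thresholds: RiskThresholds,
    drug_id: str,
    daily_dose: float,
    route: str = "oral",
) -> set[Qualifier]:
    """Risk-relevant qualifiers of one prescription at a given daily dose.

    Aspirin maps to ``LOW_DOSE_ASPIRIN`` at <= ``aspirin_low_dose_max``
    mg/day, otherwise to ``ANTIPLATELET``. Anticoagulants qualify as
    ``THERAPEUTIC_AC`` only at or above the agent's configured threshold;
    corticosteroids as ``CORTICOSTEROID_GE10`` only at or above the
    prednisone-equivalent cut-off. Other classes pass through unchanged;
    unclassified drugs yield the empty set.
    """
    if daily_dose < 0:
        raise KBError(f"negative daily dose for {drug_id}")
    base = classify_drug(kb, drug_id)
    if base is BaseClass.OTHER:
        return set()
    if base is BaseClass.NSAID:
        return {Qualifier.NSAID}
    if base is BaseClass.COX2:
        return {Qualifier.COX2}
    if base is BaseClass.SSRI:
        return {Qualifier.SSRI}
    if base is BaseClass.PPI:
        return {Qualifier.PPI}
    if base is BaseClass.ASPIRIN:
        if daily_dose <= kb.aspirin_low_dose_max:
            return {Qualifier.LOW_DOSE_ASPIRIN}
        return {Qualifier.ANTIPLATELET}
    if base is BaseClass.ANTIPLATELET_NON_ASPIRIN:
        return {Qualifier.ANTIPLATELET}
    if base is BaseClass.ANTICOAGULANT:
        code = _resolve(kb, drug_id)
        threshold = _longest_prefix(kb.anticoagulant_thresholds, code)
        if threshold is None:
            raise KBError(
                f"anticoagulant {drug_id} has no therapeutic-dose threshold"
            )
        if daily_dose >= float(threshold):
            return {Qualifier.THERAPEUTIC_AC}
        return set()
    if base is BaseClass.CORTICOSTEROID:
        eq = prednisone_equivalent(kb, drug_id, daily_dose)
        if eq >= thresholds.corticosteroid_min_prednisone_eq:
            return {Qualifier.CORTICOSTEROID_GE10}
        return set()
    raise KBError(f"unhandled base class {base}")  # pragma: no cover


def load_kb(path: str | Path | None = None) -> DrugClassKB:
    """Load a knowledge base from YAML; packaged default when ``path`` is None."""
    if path is None:
        text = (
            resources.files("ppisentinel.data")
            .joinpath("default_kb.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    limits = raw.pop("limits", {})
    return DrugClassKB(
        version=raw.get("version", "unversioned"),
        classes=raw.get("classes", {}),
        aliases=raw.get("aliases", {}),
        corticosteroid_potency=raw.get("corticosteroid_potency", {}),
        anticoagulant_thresholds=raw.get("anticoagulant_thresholds", {}),
        **({"aspirin_low_dose_max": limits["aspirin_low_dose_max"]} if "aspirin_low_dose_max" in limits else {}),
    )


def save_kb(kb: DrugClassKB, path: str | Path) -> None:
    """Serialise a knowledge base back to the YAML document layout."""
    doc = {
        "version": kb.version,
        "classes": {c: k.value for c, k in kb.classes.items()},
        "aliases": dict(kb.aliases),
        "corticosteroid_potency": dict(kb.corticosteroid_potency),
        "anticoagulant_thresholds": dict(kb.anticoagulant_thresholds),
        "limits": {"aspirin_low_dose_max": kb.aspirin_low_dose_max},
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=True), encoding="utf-8"
    )


def default_kb() -> DrugClassKB:
    """The versioned knowledge base shipped with the package."""
    return load_kb(None)
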