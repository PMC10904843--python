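"""Fabry-disease screening rule.

A patient is flagged as a suspect when they are under 50 years old and have
problem-list evidence in at least two of five organ systems (kidney,
cardiac, neuro, skin, eye), each system defined by a list of phenotype
value sets. Patients matching the Fabry diagnosis value set are reported as
known cases and never as suspects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .ehr_model import Cohort, DataWindow, PatientRecord, ProblemEntry, age_at
from .errors import ConfigurationError
from .valuesets import FABRY_DX_SET, ValueSet, ValueSetCatalog, matches

#: Canonical order of the five organ systems.
SYSTEMS = ("kidney", "cardiac", "neuro", "skin", "eye")

#: Strict upper age bound for suspects ("less than 50 years old").
MAX_SUSPECT_AGE = 50

DEFAULT_SYSTEM_MAP: dict[str, list[str]] = {
    "kidney": ["chronic kidney disease", "proteinuria", "microalbuminuria"],
    "cardiac": ["cardiomyopathy", "valvular heart disease", "arrhythmia"],
    "neuro": ["stroke ischemic", "transient ischemic attack", "acroparaesthesia"],
    "skin": ["angiokeratomas", "impaired sweating/hypohidrosis", "heat and cold tolerance"],
    "eye": ["corneal whirling", "cornea verticillata",
            "corneal and lenticular opacities", "vasculopathy (retina, conjunctiva)"],
}


class ScreenStatus(str, Enum):
    KNOWN_CASE = "known_case"
    SUSPECT = "suspect"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class SystemMap:
    """Mapping organ system → list of phenotype value-set names."""

    systems: dict[str, list[str]]

    def __post_init__(self) -> None:
        if set(self.systems) != set(SYSTEMS):
            raise ConfigurationError(
                f"system map must define exactly the systems {SYSTEMS}, "
                f"got {sorted(self.systems)}"
            )

    def validate(self, catalog: ValueSetCatalog) -> None:
        for system, names in self.systems.items():
            for name in names:
                if name not in catalog:
                    raise ConfigurationError(
                        f"system {system!r} references unknown value set {name!r}"
                    )

    @classmethod
    def default(cls) -> "SystemMap":
        return cls({k: list(v) for k, v in DEFAULT_SYSTEM_MAP.items()})


@dataclass(frozen=True)
class FabryScreenResult:
    patient_id: str
    status: ScreenStatus
    affected_systems: frozenset[str]
    age_at_reference: int


@dataclass
class FabryConfig:
    """Configuration for the Fabry cohort screen."""

    catalog: ValueSetCatalog
    system_map: SystemMap
    window: DataWindow
    dx_set: str = FABRY_DX_SET
    #: restrict problem entries to the window; configurable because it is
    #: unclear whether out-of-window history should be visible at all
    filter_to_window: bool = True


@dataclass
class ScreenSummary:
    n_known: int = 0
    n_suspect: int = 0
    n_negative: int = 0


def assign_systems(
    problems: list[ProblemEntry],
    system_map: SystemMap,
    catalog: ValueSetCatalog,
) -> set[str]:
    """The set of organ systems with at least one matching problem entry.

    A system is affected iff ≥1 entry matches ≥1 of its value sets; entry
    multiplicity within a system is irrelevant.
    """
    system_map.validate(catalog)
    affected: set[str] = set()
    for system, names in system_map.systems.items():
        sets: list[ValueSet] = [catalog[name] for name in names]
        if any(matches(vs, entry) for entry in problems for vs in sets):
            affected.add(system)
    return affected


def flag_fabry(
    patient: PatientRecord,
    problems: list[ProblemEntry],
    system_map: SystemMap,
    catalog: ValueSetCatalog,
    fabry_dx_valueset: ValueSet,
    window: DataWindow,
    filter_to_window: bool = True,
) -> FabryScreenResult:
    """Classify one patient as known case, suspect, or negative.

    A diagnosis-value-set match preempts suspect status; otherwise the
    patient is a suspect iff age at the window end is strictly under 50 and
    at least two organ systems are affected.
    """
    if filter_to_window:
        problems = [e for e in problems if window.contains(e.entry_date)]
    age = age_at(patient.date_of_birth, window.end)
    affected = frozenset(assign_systems(problems, system_map, catalog))

    if any(matches(fabry_dx_valueset, e) for e in problems):
        status = ScreenStatus.KNOWN_CASE
    elif age < MAX_SUSPECT_AGE and len(affected) >= 2:
        status = ScreenStatus.SUSPECT
    else:
        status = ScreenStatus.NEGATIVE
    return FabryScreenResult(patient.patient_id, status, affected, age)


def screen_fabry_cohort(
    cohort: Cohort, config: FabryConfig
) -> tuple[list[FabryScreenResult], ScreenSummary]:
    """Screen every patient in the cohort; returns per-patient results plus
    status tallies."""
    config.system_map.validate(config.catalog)
    dx_set = config.catalog[config.dx_set]

    by_patient: dict[str, list[ProblemEntry]] = {p.patient_id: [] for p in cohort.patients}
    for entry in cohort.problems:
        by_patient.setdefault(entry.patient_id, []).append(entry)

    results = [
        flag_fabry(
            patient,
            by_patient[patient.patient_id],
            config.system_map,
            config.catalog,
            dx_set,
            config.window,
            config.filter_to_window,
        )
        for patient in cohort.patients
    ]
    tally = Counter(r.status for r in results)
    summary = ScreenSummary(
        n_known=tally[ScreenStatus.KNOWN_CASE],
        n_suspect=tally[ScreenStatus.SUSPECT],
        n_negative=tally[ScreenStatus.NEGATIVE],
    )
    return results, summary
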