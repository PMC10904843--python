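"""Familial-hypercholesterolaemia screening rules.

A patient is a suspect when any of five disjunctive rules fires:

* premature ASCVD — earliest atherosclerotic event before age 55 (male)
  or 60 (female);
* LDL-C > 2.6 mmol/L while on a high-intensity statin covering the draw;
* LDL-C > 3.9 mmol/L at age ≤ 18 (age at the draw date);
* LDL-C > 4.9 mmol/L at age > 18.

All thresholds are strict. A patient exactly 18 years old at a draw is
evaluated only by the child rule. Known cases (FH diagnosis value-set
match) preempt suspect status.

"Adhering to" a statin is operationalised as an active order at or above
the high-intensity minimum dose whose interval covers the draw date; the
structured data has no refill granularity, so no proportion-of-days-covered
is attempted.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field

import yaml

from .ehr_model import (
    Analyte,
    Cohort,
    DataWindow,
    LabResult,
    MedicationOrder,
    PatientRecord,
    ProblemEntry,
    Sex,
    age_at,
)
from .errors import ConfigurationError
from .fabry_screen import ScreenStatus, ScreenSummary
from .valuesets import ASCVD_SET, FH_DX_SET, ValueSet, ValueSetCatalog, matches

logger = logging.getLogger(__name__)

RULE_ASCVD_MALE = "ascvd_male_lt55"
RULE_ASCVD_FEMALE = "ascvd_female_lt60"
RULE_LDL_STATIN = "ldl_statin_gt2.6"
RULE_LDL_CHILD = "ldl_child_gt3.9"
RULE_LDL_ADULT = "ldl_adult_gt4.9"

ALL_RULES = (RULE_ASCVD_MALE, RULE_ASCVD_FEMALE, RULE_LDL_STATIN,
             RULE_LDL_CHILD, RULE_LDL_ADULT)

#: ACC/AHA-style high-intensity regimens: drug → minimum daily dose (mg).
DEFAULT_HIGH_INTENSITY = {"atorvastatin": 40.0, "rosuvastatin": 20.0}


@dataclass(frozen=True)
class FHRules:
    """Thresholds for the FH screen (defaults as printed; reconfigurable)."""

    ascvd_age_male: int = 55
    ascvd_age_female: int = 60
    ldl_on_statin: float = 2.6
    ldl_child: float = 3.9
    ldl_adult: float = 4.9
    child_max_age: int = 18
    high_intensity_statins: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HIGH_INTENSITY)
    )

    def __post_init__(self) -> None:
        for name, value in [("ldl_on_statin", self.ldl_on_statin),
                            ("ldl_child", self.ldl_child),
                            ("ldl_adult", self.ldl_adult)]:
            if value <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if not self.ldl_on_statin < self.ldl_child < self.ldl_adult:
            logger.warning(
                "FH thresholds do not satisfy statin < child < adult ordering: "
                "%s, %s, %s", self.ldl_on_statin, self.ldl_child, self.ldl_adult,
            )

    @classmethod
    def from_yaml(cls, path) -> "FHRules":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"FH rules file {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown FH rule field(s): {sorted(unknown)}")
        if "high_intensity_statins" in raw:
            raw["high_intensity_statins"] = {
                str(k).lower(): float(v) for k, v in raw["high_intensity_statins"].items()
            }
        return cls(**raw)


@dataclass(frozen=True)
class FHScreenResult:
    patient_id: str
    status: ScreenStatus
    triggered_rules: frozenset[str]
    qualifying_ldl: float | None


@dataclass
class FHConfig:
    """Configuration for the FH cohort screen."""

    catalog: ValueSetCatalog
    window: DataWindow
    rules: FHRules = field(default_factory=FHRules)
    dx_set: str = FH_DX_SET
    ascvd_set: str = ASCVD_SET
    filter_to_window: bool = True


def is_premature_ascvd(
    patient: PatientRecord,
    problems: list[ProblemEntry],
    ascvd_valueset: ValueSet,
    window: DataWindow,
    rules: FHRules | None = None,
) -> tuple[bool, str | None]:
    """Premature-ASCVD rule: age at the EARLIEST matching event strictly
    below the sex-specific bound. Unknown sex → rule not applicable."""
    rules = rules or FHRules()
    if patient.sex is Sex.UNKNOWN:
        logger.info("patient %s: unknown sex, ASCVD rule skipped", patient.patient_id)
        return False, None
    dates = [e.entry_date for e in problems if matches(ascvd_valueset, e)]
    if not dates:
        return False, None
    onset_age = age_at(patient.date_of_birth, min(dates))
    if patient.sex is Sex.MALE and onset_age < rules.ascvd_age_male:
        return True, RULE_ASCVD_MALE
    if patient.sex is Sex.FEMALE and onset_age < rules.ascvd_age_female:
        return True, RULE_ASCVD_FEMALE
    return False, None


def on_high_intensity_statin(
    meds: list[MedicationOrder], date: dt.date, rules: FHRules | None = None
) -> bool:
    """True iff some order in the high-intensity list, at or above its
    minimum dose, covers *date* (open-ended orders stay active)."""
    rules = rules or FHRules()
    for order in meds:
        min_dose = rules.high_intensity_statins.get(order.drug_name.strip().lower())
        if min_dose is not None and order.dose_mg >= min_dose and order.covers(date):
            return True
    return False


def flag_fh(
    patient: PatientRecord,
    problems: list[ProblemEntry],
    labs: list[LabResult],
    meds: list[MedicationOrder],
    rules: FHRules,
    fh_dx_valueset: ValueSet,
    ascvd_valueset: ValueSet,
    window: DataWindow,
    filter_to_window: bool = True,
) -> FHScreenResult:
    """Classify one patient against the five FH rules.

    ``qualifying_ldl`` is the maximum LDL-C among results that fired a rule
    (absent when only the ASCVD rule fired).
    """
    if filter_to_window:
        problems = [e for e in problems if window.contains(e.entry_date)]
        labs = [lab for lab in labs if window.contains(lab.draw_date)]

    if any(matches(fh_dx_valueset, e) for e in problems):
        return FHScreenResult(patient.patient_id, ScreenStatus.KNOWN_CASE,
                              frozenset(), None)

    triggered: set[str] = set()
    qualifying: list[float] = []

    for lab in labs:
        if lab.analyte is not Analyte.LDL_C:
            continue
        if lab.units.strip().lower() not in {"mmol/l"}:
            logger.warning(
                "patient %s: LDL-C result in unconvertible units %r skipped",
                patient.patient_id, lab.units,
            )
            continue
        draw_age = age_at(patient.date_of_birth, lab.draw_date)
        fired = False
        if lab.value > rules.ldl_on_statin and on_high_intensity_statin(
            meds, lab.draw_date, rules
        ):
            triggered.add(RULE_LDL_STATIN)
            fired = True
        if draw_age <= rules.child_max_age:
            if lab.value > rules.ldl_child:
                triggered.add(RULE_LDL_CHILD)
                fired = True
        elif lab.value > rules.ldl_adult:
            triggered.add(RULE_LDL_ADULT)
            fired = True
        if fired:
            qualifying.append(lab.value)

    ascvd, rule = is_premature_ascvd(patient, problems, ascvd_valueset, window, rules)
    if ascvd and rule is not None:
        triggered.add(rule)

    status = ScreenStatus.SUSPECT if triggered else ScreenStatus.NEGATIVE
    return FHScreenResult(
        patient.patient_id,
        status,
        frozenset(triggered),
        max(qualifying) if qualifying else None,
    )


def screen_fh_cohort(
    cohort: Cohort, config: FHConfig
) -> tuple[list[FHScreenResult], ScreenSummary]:
    """Screen every patient in the cohort; returns per-patient results plus
    status tallies."""
    dx_set = config.catalog[config.dx_set]
    ascvd_set = config.catalog[config.ascvd_set]

    problems: dict[str, list[ProblemEntry]] = {p.patient_id: [] for p in cohort.patients}
    labs: dict[str, list[LabResult]] = {p.patient_id: [] for p in cohort.patients}
    meds: dict[str, list[MedicationOrder]] = {p.patient_id: [] for p in cohort.patients}
    for e in cohort.problems:
        problems.setdefault(e.patient_id, []).append(e)
    for lab in cohort.labs:
        labs.setdefault(lab.patient_id, []).append(lab)
    for m in cohort.meds:
        meds.setdefault(m.patient_id, []).append(m)

    results = [
        flag_fh(
            patient,
            problems[patient.patient_id],
            labs[patient.patient_id],
            meds[patient.patient_id],
            config.rules,
            dx_set,
            ascvd_set,
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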