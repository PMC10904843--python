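"""Synthetic structured-EHR cohort generator with a ground-truth manifest.

Stands in for the protected study data: plants known cases (diagnosis
codes), suspects (evidence constructed to satisfy the screening rules),
near-miss decoys (evidence failing exactly one rule clause), and negatives,
then emits the four EHR tables plus a manifest recording every patient's
archetype and expected screen outcome. The manifest is ground truth by
construction, so screen-recovery tests can demand exact agreement.

Default marginals mirror the study's printed cohort structure: race mix
0.61/0.155/0.117/0.118, ~60:40 male:female Fabry suspects, ~42:58 FH
suspects, suspect ages concentrated just above 40, and right-skewed
adult-suspect LDL-C hugging 4.9 mmol/L with rare extremes above 20.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ehr_model import (
    DEFAULT_WINDOW,
    Analyte,
    Cohort,
    CodeSystem,
    DataWindow,
    LabResult,
    MedicationOrder,
    PatientRecord,
    ProblemEntry,
    Race,
    Sex,
    add_years,
)
from .errors import ConfigurationError
from .fabry_screen import DEFAULT_SYSTEM_MAP, SYSTEMS, ScreenStatus
from .valuesets import ValueSetCatalog, default_catalog

ARCHETYPES = (
    "fabry_known", "fabry_suspect", "fh_known", "fh_suspect",
    "near_miss_fabry_age", "near_miss_fabry_single_system",
    "near_miss_fh_ldl_threshold", "near_miss_fh_weak_statin",
    "negative",
)

DEFAULT_RACE_PROBS = {
    Race.CHINESE: 0.61,
    Race.MALAY: 0.155,
    Race.INDIAN: 0.117,
    Race.OTHER: 0.118,
}


@dataclass
class FabrySynthConfig:
    n_known: int = 4
    n_suspect: int = 20
    suspect_male_frac: float = 0.6
    #: triangular age distribution on [age_min, 49] with this mode; the
    #: defaults put the suspect median age just above 40
    age_min: int = 25
    age_mode: float = 44.0
    #: P(2, 3, 4, 5 affected systems) for suspects
    system_multiplicity_probs: tuple[float, ...] = (0.80, 0.15, 0.04, 0.01)


@dataclass
class FHSynthConfig:
    n_known: int = 16
    n_suspect: int = 120
    suspect_female_frac: float = 0.58
    #: P(an adult-suspect LDL draw lands in the >20 mmol/L extreme tail)
    extreme_tail_prob: float = 0.01
    #: mix of planted suspect rules: (adult LDL, child LDL, statin, ASCVD)
    rule_mix: tuple[float, ...] = (0.70, 0.10, 0.10, 0.10)


@dataclass
class SyntheticConfig:
    n_patients: int = 5000
    seed: int = 0
    window: DataWindow = DEFAULT_WINDOW
    race_probs: dict[Race, float] = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    fabry: FabrySynthConfig = field(default_factory=FabrySynthConfig)
    fh: FHSynthConfig = field(default_factory=FHSynthConfig)
    #: near-miss decoy counts, keyed by decoy kind
    decoys: dict[str, int] = field(default_factory=lambda: {
        "fabry_age": 13,
        "fabry_single_system": 13,
        "fh_ldl_threshold": 12,
        "fh_weak_statin": 12,
    })

    def validate(self) -> None:
        total_planted = (
            self.fabry.n_known + self.fabry.n_suspect
            + self.fh.n_known + self.fh.n_suspect
            + sum(self.decoys.values())
        )
        if total_planted > self.n_patients:
            raise ConfigurationError(
                f"planted archetypes ({total_planted}) exceed n_patients "
                f"({self.n_patients})"
            )
        bad = set(self.decoys) - {
            "fabry_age", "fabry_single_system", "fh_ldl_threshold", "fh_weak_statin"
        }
        if bad:
            raise ConfigurationError(f"unknown decoy kind(s): {sorted(bad)}")
        total = sum(self.race_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"race probabilities sum to {total}, expected 1")
        if not all(0.0 <= p <= 1.0 for p in self.race_probs.values()):
            raise ConfigurationError("race probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    archetype: str
    expected_fabry: ScreenStatus
    expected_fh: ScreenStatus
    detail: str = ""


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: one record per generated patient."""

    records: list[TruthRecord] = field(default_factory=list)

    def by_id(self) -> dict[str, TruthRecord]:
        return {r.patient_id: r for r in self.records}

    def expected_summary(self, disease: str) -> tuple[int, int]:
        """(n_known, n_suspect) the screen for *disease* should report."""
        attr = "expected_fabry" if disease == "fabry" else "expected_fh"
        statuses = [getattr(r, attr) for r in self.records]
        return (
            sum(1 for s in statuses if s is ScreenStatus.KNOWN_CASE),
            sum(1 for s in statuses if s is ScreenStatus.SUSPECT),
        )

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "archetype", "expected_fabry", "expected_fh", "detail"])
            for r in self.records:
                w.writerow([r.patient_id, r.archetype, r.expected_fabry.value,
                            r.expected_fh.value, r.detail])

    @classmethod
    def read_csv(cls, path: str | Path) -> "SyntheticTruth":
        truth = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                truth.records.append(TruthRecord(
                    rec["patient_id"], rec["archetype"],
                    ScreenStatus(rec["expected_fabry"]),
                    ScreenStatus(rec["expected_fh"]),
                    rec["detail"],
                ))
        return truth


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def sample_ldl(archetype: str, rng: np.random.Generator,
               extreme_tail_prob: float = 0.01) -> float:
    """Draw one LDL-C value (mmol/L) for the given archetype.

    Adult-suspect draws come from a shifted log-normal with support
    strictly above 4.9 and mass concentrated near the threshold; with
    probability *extreme_tail_prob* the draw lands in the extreme
    (20, 25) band instead.
    """
    if archetype == "suspect_adult":
        if rng.random() < extreme_tail_prob:
            return float(rng.uniform(20.5, 24.5))
        return 4.9 + float(rng.lognormal(mean=-1.3, sigma=0.8))
    if archetype == "suspect_child":
        return 3.9 + float(rng.lognormal(mean=-1.3, sigma=0.6))
    if archetype == "suspect_statin":
        return float(rng.uniform(2.8, 4.4))
    if archetype == "tp":
        return 3.2 + float(rng.lognormal(mean=-0.3, sigma=0.7))
    if archetype == "negative":
        return float(rng.uniform(1.2, 2.5))
    raise ConfigurationError(f"unknown LDL archetype {archetype!r}")


def _random_date(rng: np.random.Generator, window: DataWindow,
                 earliest: dt.date | None = None) -> dt.date:
    lo = window.start if earliest is None else max(window.start, earliest)
    span = (window.end - lo).days
    return lo + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _dob_for_age(rng: np.random.Generator, age: int, reference: dt.date) -> dt.date:
    """A date of birth giving exactly *age* completed years at *reference*."""
    return add_years(reference, -age) - dt.timedelta(days=int(rng.integers(0, 365)))


def _sample_race(rng: np.random.Generator, probs: dict[Race, float]) -> Race:
    races = list(probs)
    return races[int(rng.choice(len(races), p=list(probs.values())))]


def _sample_sex(rng: np.random.Generator, male_frac: float = 0.5) -> Sex:
    return Sex.MALE if rng.random() < male_frac else Sex.FEMALE


def _set_code(catalog: ValueSetCatalog, name: str) -> tuple[CodeSystem, str]:
    """A deterministic representative code for a value set."""
    return sorted(catalog[name].codes, key=lambda c: (c[0].value, c[1]))[0]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates the tables while archetype generators run."""

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.cohort = Cohort()
        self.truth = SyntheticTruth()
        self.catalog = default_catalog()
        self._next_id = 1

    def new_patient(self, rng: np.random.Generator, sex: Sex, dob: dt.date) -> PatientRecord:
        patient = PatientRecord(
            patient_id=f"PID{self._next_id:06d}",
            sex=sex,
            race=_sample_race(rng, self.config.race_probs),
            date_of_birth=dob,
        )
        self._next_id += 1
        self.cohort.patients.append(patient)
        return patient

    def add_problem(self, patient: PatientRecord, set_name: str, date: dt.date,
                    description: str | None = None) -> None:
        system, code = _set_code(self.catalog, set_name)
        self.cohort.problems.append(ProblemEntry(
            patient_id=patient.patient_id,
            code=code,
            code_system=system,
            description=description if description is not None else set_name,
            entry_date=date,
        ))

    def add_benign_problem(self, patient: PatientRecord, rng: np.random.Generator,
                           date: dt.date) -> None:
        """Background-noise problem matching no value set (code or synonym)."""
        description = BENIGN_DESCRIPTIONS[int(rng.integers(0, len(BENIGN_DESCRIPTIONS)))]
        self.cohort.problems.append(ProblemEntry(
            patient_id=patient.patient_id,
            code=f"BENIGN{int(rng.integers(1, 100)):03d}",
            code_system=CodeSystem.LOCAL,
            description=description,
            entry_date=date,
        ))

    def add_ldl(self, patient: PatientRecord, value: float, date: dt.date) -> None:
        self.cohort.labs.append(LabResult(
            patient_id=patient.patient_id,
            analyte=Analyte.LDL_C,
            value=round(value, 3),
            units="mmol/L",
            draw_date=date,
        ))

    def add_statin(self, patient: PatientRecord, rng: np.random.Generator,
                   drug: str, dose: float, covering: dt.date) -> None:
        window = self.config.window
        start = max(window.start, covering - dt.timedelta(days=int(rng.integers(10, 200))))
        if rng.random() < 0.3:
            end = None  # open order, active through the window end
        else:
            end = min(window.end, covering + dt.timedelta(days=int(rng.integers(10, 200))))
        self.cohort.meds.append(MedicationOrder(
            patient_id=patient.patient_id,
            drug_name=drug,
            dose_mg=dose,
            start_date=start,
            end_date=end,
        ))

    def record(self, patient: PatientRecord, archetype: str,
               fabry: ScreenStatus, fh: ScreenStatus, detail: str = "") -> None:
        self.truth.records.append(TruthRecord(patient.patient_id, archetype, fabry, fh, detail))


def _plant_fabry_known(b: _Builder, rng: np.random.Generator) -> None:
    cfg, window = b.config, b.config.window
    age = int(rng.integers(20, 65))
    patient = b.new_patient(rng, _sample_sex(rng), _dob_for_age(rng, age, window.end))
    b.add_problem(patient, "fabry disease", _random_date(rng, window))
    detail = "dx"
    if rng.random() < 0.5 and age < 50:
        # suspect-like evidence on top of the diagnosis, to exercise the
        # preemption rule
        for system in ("kidney", "cardiac"):
            b.add_problem(patient, DEFAULT_SYSTEM_MAP[system][0], _random_date(rng, window))
        detail = "dx+systems"
    b.record(patient, "fabry_known", ScreenStatus.KNOWN_CASE, ScreenStatus.NEGATIVE, detail)


def _plant_fabry_suspect(b: _Builder, rng: np.random.Generator) -> None:
    cfg, window = b.config.fabry, b.config.window
    age = min(49, int(rng.triangular(cfg.age_min, cfg.age_mode, 50)))
    patient = b.new_patient(
        rng, _sample_sex(rng, cfg.suspect_male_frac), _dob_for_age(rng, age, window.end)
    )
    probs = np.asarray(cfg.system_multiplicity_probs, dtype=float)
    n_systems = 2 + int(rng.choice(len(probs), p=probs / probs.sum()))
    systems = [SYSTEMS[i] for i in sorted(rng.choice(5, size=n_systems, replace=False))]
    for system in systems:
        names = DEFAULT_SYSTEM_MAP[system]
        name = names[int(rng.integers(0, len(names)))]
        b.add_problem(patient, name, _random_date(rng, window))
        if rng.random() < 0.2:  # duplicate row; must not change the outcome
            b.add_problem(patient, name, _random_date(rng, window))
    if rng.random() < 0.3:
        b.add_ldl(patient, sample_ldl("negative", rng),
                  _random_date(rng, window, patient.date_of_birth))
    b.record(patient, "fabry_suspect", ScreenStatus.SUSPECT, ScreenStatus.NEGATIVE,
             ";".join(systems))


def _plant_fh_known(b: _Builder, rng: np.random.Generator) -> None:
    window = b.config.window
    age = int(rng.integers(25, 70))
    patient = b.new_patient(rng, _sample_sex(rng, 0.53), _dob_for_age(rng, age, window.end))
    b.add_problem(patient, "familial hypercholesterolaemia", _random_date(rng, window))
    for _ in range(int(rng.integers(1, 4))):
        b.add_ldl(patient, sample_ldl("tp", rng), _random_date(rng, window))
    b.record(patient, "fh_known", ScreenStatus.NEGATIVE, ScreenStatus.KNOWN_CASE, "dx")


def _plant_fh_suspect(b: _Builder, rng: np.random.Generator) -> None:
    cfg, window = b.config.fh, b.config.window
    mix = np.asarray(cfg.rule_mix, dtype=float)
    kind = ("adult", "child", "statin", "ascvd")[int(rng.choice(4, p=mix / mix.sum()))]
    sex = _sample_sex(rng, 1.0 - cfg.suspect_female_frac)

    if kind == "adult":
        age = int(rng.integers(20, 80))
        patient = b.new_patient(rng, sex, _dob_for_age(rng, age, window.end))
        value = sample_ldl("suspect_adult", rng, cfg.extreme_tail_prob)
        b.add_ldl(patient, value, _random_date(rng, window))
        detail = f"ldl_adult:{value:.2f}"
    elif kind == "child":
        age = int(rng.integers(8, 18))
        patient = b.new_patient(rng, sex, _dob_for_age(rng, age, window.end))
        value = sample_ldl("suspect_child", rng)
        b.add_ldl(patient, value, _random_date(rng, window, patient.date_of_birth))
        detail = f"ldl_child:{value:.2f}"
    elif kind == "statin":
        age = int(rng.integers(25, 75))
        patient = b.new_patient(rng, sex, _dob_for_age(rng, age, window.end))
        value = sample_ldl("suspect_statin", rng)
        draw = _random_date(rng, window)
        b.add_ldl(patient, value, draw)
        drug, dose = [("atorvastatin", 40.0), ("atorvastatin", 80.0),
                      ("rosuvastatin", 20.0), ("rosuvastatin", 40.0)][int(rng.integers(0, 4))]
        b.add_statin(patient, rng, drug, dose, draw)
        detail = f"ldl_statin:{value:.2f}"
    else:  # premature ASCVD
        onset_bound = 55 if sex is Sex.MALE else 60
        onset = int(rng.integers(30, onset_bound))
        event = _random_date(rng, window)
        dob = _dob_for_age(rng, onset, event)
        patient = b.new_patient(rng, sex, dob)
        b.add_problem(patient, "ascvd", event, description="myocardial infarction")
        detail = f"ascvd:{onset}"
    b.record(patient, "fh_suspect", ScreenStatus.NEGATIVE, ScreenStatus.SUSPECT, detail)


def _plant_decoy(b: _Builder, rng: np.random.Generator, kind: str) -> None:
    """Near-miss decoys: evidence failing exactly one rule clause."""
    window = b.config.window
    if kind == "fabry_age":
        # two systems but exactly at the 50-year boundary ("less than 50")
        patient = b.new_patient(rng, _sample_sex(rng), _dob_for_age(rng, 50, window.end))
        for system in rng.choice(5, size=2, replace=False):
            names = DEFAULT_SYSTEM_MAP[SYSTEMS[int(system)]]
            b.add_problem(patient, names[int(rng.integers(0, len(names)))],
                          _random_date(rng, window))
    elif kind == "fabry_single_system":
        # under 50 but only one affected system, despite several entries
        age = int(rng.integers(18, 50))
        patient = b.new_patient(rng, _sample_sex(rng), _dob_for_age(rng, age, window.end))
        names = DEFAULT_SYSTEM_MAP[SYSTEMS[int(rng.integers(0, 5))]]
        for _ in range(int(rng.integers(2, 4))):
            b.add_problem(patient, names[int(rng.integers(0, len(names)))],
                          _random_date(rng, window))
    elif kind == "fh_ldl_threshold":
        # adult with LDL exactly at the 4.9 threshold (rule is strict >)
        age = int(rng.integers(25, 75))
        patient = b.new_patient(rng, _sample_sex(rng), _dob_for_age(rng, age, window.end))
        b.add_ldl(patient, 4.9, _random_date(rng, window))
    elif kind == "fh_weak_statin":
        # elevated LDL on a statin below the high-intensity minimum dose
        age = int(rng.integers(25, 75))
        patient = b.new_patient(rng, _sample_sex(rng), _dob_for_age(rng, age, window.end))
        value = float(rng.uniform(3.0, 4.5))
        draw = _random_date(rng, window)
        b.add_ldl(patient, value, draw)
        b.add_statin(patient, rng, "atorvastatin", 20.0, draw)
    else:  # pragma: no cover - guarded by SyntheticConfig.validate
        raise ConfigurationError(f"unknown decoy kind {kind!r}")
    b.record(patient, f"near_miss_{kind}", ScreenStatus.NEGATIVE, ScreenStatus.NEGATIVE, kind)


def _plant_negative(b: _Builder, rng: np.random.Generator) -> None:
    window = b.config.window
    age = int(rng.integers(1, 90))
    patient = b.new_patient(rng, _sample_sex(rng), _dob_for_age(rng, age, window.end))
    roll = rng.random()
    if roll < 0.3:
        b.add_benign_problem(patient, rng, _random_date(rng, window))
    elif roll < 0.5:
        b.add_ldl(patient, sample_ldl("negative", rng),
                  _random_date(rng, window, patient.date_of_birth))
    b.record(patient, "negative", ScreenStatus.NEGATIVE, ScreenStatus.NEGATIVE)


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, SyntheticTruth]:
    """Generate the four EHR tables plus the ground-truth manifest.

    Deterministic given ``config.seed``; every planted archetype's
    evidence satisfies (or, for near-misses, violates by exactly one
    clause) the corresponding screen rule.
    """
    config.validate()
    # independent substreams so adding one archetype family does not
    # perturb the draws of another
    streams = {
        name: np.random.default_rng([config.seed, i])
        for i, name in enumerate(["fabry", "fh", "decoys", "negatives"])
    }
    b = _Builder(config)

    for _ in range(config.fabry.n_known):
        _plant_fabry_known(b, streams["fabry"])
    for _ in range(config.fabry.n_suspect):
        _plant_fabry_suspect(b, streams["fabry"])
    for _ in range(config.fh.n_known):
        _plant_fh_known(b, streams["fh"])
    for _ in range(config.fh.n_suspect):
        _plant_fh_suspect(b, streams["fh"])
    for kind, count in sorted(config.decoys.items()):
        for _ in range(count):
            _plant_decoy(b, streams["decoys"], kind)
    n_planted = len(b.cohort.patients)
    for _ in range(config.n_patients - n_planted):
        _plant_negative(b, streams["negatives"])

    return b.cohort, b.truth


# problem descriptions that never match any default value set, usable as
# background noise by callers
BENIGN_DESCRIPTIONS = ("essential hypertension", "type 2 diabetes mellitus",
                       "osteoarthritis", "gastritis")
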