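"""Domain types and I/O for the four structured-EHR tables.

The pipeline works on four flat CSV tables (UTF-8, header row required):

* ``patients.csv``  — ``patient_id,sex,race,date_of_birth``
* ``problems.csv``  — ``patient_id,code,code_system,description,entry_date``
* ``labs.csv``      — ``patient_id,analyte,value,units,draw_date``
* ``meds.csv``      — ``patient_id,drug_name,dose_mg,start_date,end_date``

Rows that violate the documented schema (malformed dates, unknown enum
values, negative lab values, orphan patient ids, ...) are rejected with a
row-level diagnostic rather than silently coerced.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)

#: mg/dL per mmol/L for cholesterol; used to normalise mixed-unit LDL-C.
MG_DL_PER_MMOL_L = 38.67


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Race(str, Enum):
    CHINESE = "chinese"
    MALAY = "malay"
    INDIAN = "indian"
    OTHER = "other"
    UNKNOWN = "unknown"


class CodeSystem(str, Enum):
    SNOMED = "SNOMED"
    LOCAL = "local"


class Analyte(str, Enum):
    LDL_C = "LDL_C"
    OTHER = "other"


@dataclass(frozen=True)
class PatientRecord:
    """One person: pseudonymous id, sex, race, date of birth."""

    patient_id: str
    sex: Sex
    race: Race
    date_of_birth: dt.date


@dataclass(frozen=True)
class ProblemEntry:
    """One coded problem-list entry for a patient."""

    patient_id: str
    code: str
    code_system: CodeSystem
    description: str
    entry_date: dt.date


@dataclass(frozen=True)
class LabResult:
    """One laboratory result; LDL-C values are stored in mmol/L."""

    patient_id: str
    analyte: Analyte
    value: float
    units: str
    draw_date: dt.date


@dataclass(frozen=True)
class MedicationOrder:
    """One medication order; an absent end date means the order is open."""

    patient_id: str
    drug_name: str
    dose_mg: float
    start_date: dt.date
    end_date: dt.date | None = None

    def covers(self, date: dt.date) -> bool:
        """True if *date* falls inside the order interval.

        An open-ended order (no end date) is treated as active from its
        start date onwards.
        """
        if date < self.start_date:
            return False
        return self.end_date is None or date <= self.end_date


@dataclass(frozen=True)
class DataWindow:
    """Half-open-at-neither-end observation window [start, end]."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(f"window start {self.start} must precede end {self.end}")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


#: The study-style default observation window (1 Jan 2018 – 1 Mar 2022).
DEFAULT_WINDOW = DataWindow(dt.date(2018, 1, 1), dt.date(2022, 3, 1))


@dataclass
class Cohort:
    """The four tables of one cohort, fully parsed and validated."""

    patients: list[PatientRecord] = field(default_factory=list)
    problems: list[ProblemEntry] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    meds: list[MedicationOrder] = field(default_factory=list)

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}


@dataclass(frozen=True)
class RowReject:
    """Row-level diagnostic for a rejected input row (1-based data rows)."""

    table: str
    row: int
    reason: str


# ---------------------------------------------------------------------------
# Date / age utilities
# ---------------------------------------------------------------------------

def add_years(date: dt.date, years: int) -> dt.date:
    """Shift a date by whole years; 29 Feb maps to 1 Mar in non-leap years."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:
        return dt.date(date.year + years, 3, 1)


def age_at(dob: dt.date, reference: dt.date) -> int:
    """Completed years of age at *reference*.

    The birthday itself counts as completed (dob 2000-06-15 is age 50 on
    2050-06-15). Raises :class:`DataError` if dob is after the reference.
    """
    if dob > reference:
        raise DataError(f"date of birth {dob} is after reference date {reference}")
    age = reference.year - dob.year
    if add_years(dob, age) > reference:
        age -= 1
    return age


# ---------------------------------------------------------------------------
# Pseudonymisation
# ---------------------------------------------------------------------------

def pseudonymise(ids: list[str], seed: int) -> dict[str, str]:
    """Map original identifiers to opaque ``PIDxxxxxx`` identifiers.

    The inputs are randomly permuted with a seeded generator and PID
    numbers are assigned in permuted order, so the numeric part carries no
    information about the original sort order.
    """
    if len(set(ids)) != len(ids):
        raise DataError("duplicate input ids passed to pseudonymise")
    if len(ids) > 999_999:
        raise DataError("PID format supports at most 999,999 identifiers")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[int(i)]: f"PID{j + 1:06d}" for j, i in enumerate(order)}


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ["patient_id", "sex", "race", "date_of_birth"]
PROBLEM_COLUMNS = ["patient_id", "code", "code_system", "description", "entry_date"]
LAB_COLUMNS = ["patient_id", "analyte", "value", "units", "draw_date"]
MED_COLUMNS = ["patient_id", "drug_name", "dose_mg", "start_date", "end_date"]


def _parse_date(text: str, what: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise ValueError(f"malformed {what} {text!r} (expected YYYY-MM-DD)") from None


def _read_table(path: Path, columns: list[str], table: str):
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != columns:
            raise DataError(
                f"{table}: header {reader.fieldnames} does not match expected {columns}"
            )
        yield from enumerate(reader, start=1)


def _parse_patient(rec: dict) -> PatientRecord:
    return PatientRecord(
        patient_id=rec["patient_id"].strip(),
        sex=Sex(rec["sex"].strip().lower()),
        race=Race(rec["race"].strip().lower()),
        date_of_birth=_parse_date(rec["date_of_birth"], "date_of_birth"),
    )


def _parse_problem(rec: dict) -> ProblemEntry:
    code = rec["code"].strip()
    if not code:
        raise ValueError("empty code")
    return ProblemEntry(
        patient_id=rec["patient_id"].strip(),
        code=code,
        code_system=CodeSystem(rec["code_system"].strip()),
        description=rec["description"],
        entry_date=_parse_date(rec["entry_date"], "entry_date"),
    )


def _parse_lab(rec: dict) -> LabResult:
    analyte = Analyte(rec["analyte"].strip())
    value = float(rec["value"])
    units = rec["units"].strip()
    if value < 0:
        raise ValueError(f"negative lab value {value}")
    if analyte is Analyte.LDL_C and units.lower() == "mg/dl":
        # mixed-unit EHR input: normalise to the threshold scale
        value = value / MG_DL_PER_MMOL_L
        units = "mmol/L"
        logger.info("labs: converted LDL-C value from mg/dL to mmol/L")
    return LabResult(
        patient_id=rec["patient_id"].strip(),
        analyte=analyte,
        value=value,
        units=units,
        draw_date=_parse_date(rec["draw_date"], "draw_date"),
    )


def _parse_med(rec: dict) -> MedicationOrder:
    dose = float(rec["dose_mg"])
    if dose <= 0:
        raise ValueError(f"non-positive dose {dose}")
    start = _parse_date(rec["start_date"], "start_date")
    end_text = rec["end_date"].strip()
    end = _parse_date(end_text, "end_date") if end_text else None
    if end is not None and start > end:
        raise ValueError(f"start_date {start} after end_date {end}")
    return MedicationOrder(
        patient_id=rec["patient_id"].strip(),
        drug_name=rec["drug_name"].strip(),
        dose_mg=dose,
        start_date=start,
        end_date=end,
    )


def read_cohort(
    patients_path: str | Path,
    problems_path: str | Path,
    labs_path: str | Path,
    meds_path: str | Path,
) -> tuple[Cohort, list[RowReject]]:
    """Read and validate the four cohort tables.

    Returns the parsed :class:`Cohort` plus a list of :class:`RowReject`
    diagnostics, one per rejected row. Rows referencing a patient_id not
    present in the patients table are rejected (referential integrity).
    """
    cohort = Cohort()
    rejects: list[RowReject] = []

    seen_ids: set[str] = set()
    for row, rec in _read_table(Path(patients_path), PATIENT_COLUMNS, "patients"):
        try:
            patient = _parse_patient(rec)
            if patient.patient_id in seen_ids:
                raise ValueError(f"duplicate patient_id {patient.patient_id!r}")
        except (ValueError, KeyError) as exc:
            rejects.append(RowReject("patients", row, str(exc)))
            continue
        seen_ids.add(patient.patient_id)
        cohort.patients.append(patient)

    tables = [
        ("problems", Path(problems_path), PROBLEM_COLUMNS, _parse_problem, cohort.problems),
        ("labs", Path(labs_path), LAB_COLUMNS, _parse_lab, cohort.labs),
        ("meds", Path(meds_path), MED_COLUMNS, _parse_med, cohort.meds),
    ]
    for table, path, columns, parse, out in tables:
        for row, rec in _read_table(path, columns, table):
            try:
                record = parse(rec)
                if record.patient_id not in seen_ids:
                    raise ValueError(f"unknown patient_id {record.patient_id!r}")
            except (ValueError, KeyError) as exc:
                rejects.append(RowReject(table, row, str(exc)))
                continue
            out.append(record)

    for reject in rejects:
        logger.warning("%s row %d rejected: %s", reject.table, reject.row, reject.reason)
    return cohort, rejects


def read_cohort_dir(directory: str | Path) -> tuple[Cohort, list[RowReject]]:
    """Read a cohort from a directory holding the four conventionally
    named CSVs (patients.csv, problems.csv, labs.csv, meds.csv)."""
    d = Path(directory)
    return read_cohort(d / "patients.csv", d / "problems.csv", d / "labs.csv", d / "meds.csv")


def _fmt_date(date: dt.date | None) -> str:
    return date.isoformat() if date is not None else ""


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the four tables to *directory*; returns table name → path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {name: d / f"{name}.csv" for name in ("patients", "problems", "labs", "meds")}

    with open(paths["patients"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in cohort.patients:
            w.writerow([p.patient_id, p.sex.value, p.race.value, _fmt_date(p.date_of_birth)])

    with open(paths["problems"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PROBLEM_COLUMNS)
        for e in cohort.problems:
            w.writerow([e.patient_id, e.code, e.code_system.value, e.description,
                        _fmt_date(e.entry_date)])

    with open(paths["labs"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LAB_COLUMNS)
        for lab in cohort.labs:
            w.writerow([lab.patient_id, lab.analyte.value, repr(lab.value), lab.units,
                        _fmt_date(lab.draw_date)])

    with open(paths["meds"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MED_COLUMNS)
        for m in cohort.meds:
            w.writerow([m.patient_id, m.drug_name, repr(m.dose_mg),
                        _fmt_date(m.start_date), _fmt_date(m.end_date)])

    return paths
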