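import datetime as dt

import pytest

from raredetect.ehr_model import (
    DataWindow,
    PatientRecord,
    ProblemEntry,
    Race,
    Sex,
    CodeSystem,
)
from raredetect.valuesets import default_catalog

WINDOW = DataWindow(dt.date(2018, 1, 1), dt.date(2022, 3, 1))


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def window():
    return WINDOW


def make_patient(pid="PID000001", sex=Sex.MALE, race=Race.CHINESE,
                 dob=dt.date(1980, 6, 15)) -> PatientRecord:
    return PatientRecord(pid, sex, race, dob)


def make_problem(pid="PID000001", code="X", system=CodeSystem.LOCAL,
                 description="", date=dt.date(2020, 1, 1)) -> ProblemEntry:
    return ProblemEntry(pid, code, system, description, date)
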