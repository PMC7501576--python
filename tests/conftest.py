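import datetime as dt

import pytest
from hypothesis import settings

from pediphen import (
    AlgorithmConfig,
    AlgorithmVersion,
    DxEvent,
    LabEvent,
    MedEvent,
    PatientRecord,
    default_catalog,
)

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

INDEX = dt.date(2016, 12, 31)
DX_DAY = dt.date(2016, 6, 1)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def config_v1():
    return AlgorithmConfig(version=AlgorithmVersion.V1)


def make_patient(
    *,
    t1_codes=0,
    t2_codes=0,
    insulin_offset_days=None,
    glucose=None,
    hba1c=None,
    metformin=False,
    other_code=None,
    birth=dt.date(2005, 3, 15),
    patient_id="X1",
    extra_dx=(),
) -> PatientRecord:
    """Build a minimal synthetic patient around a fixed diagnosis day."""
    dxs = []
    for i in range(t1_codes):
        dxs.append(DxEvent(DX_DAY + dt.timedelta(days=i), "E10.9", "ICD10", "outpatient"))
    for i in range(t2_codes):
        dxs.append(DxEvent(DX_DAY + dt.timedelta(days=i), "E11.9", "ICD10", "outpatient"))
    if other_code:
        dxs.append(DxEvent(DX_DAY, other_code, "ICD10", "outpatient"))
    for code in extra_dx:
        dxs.append(DxEvent(DX_DAY, code, "ICD10", "outpatient"))
    labs = []
    if glucose is not None:
        labs.append(LabEvent(DX_DAY, "GLUCOSE", glucose))
    if hba1c is not None:
        labs.append(LabEvent(DX_DAY, "HBA1C", hba1c))
    meds = []
    if insulin_offset_days is not None:
        meds.append(
            MedEvent(DX_DAY + dt.timedelta(days=insulin_offset_days), "INSULIN", "insulin glargine")
        )
    if metformin:
        meds.append(MedEvent(DX_DAY, "METFORMIN", "metformin hydrochloride"))
    rec = PatientRecord(
        patient_id=patient_id, birth_date=birth, sex="F", race="Caucasian",
        ethnicity="Not Hispanic", diagnoses=dxs, labs=labs, meds=meds,
    )
    rec.sort_events()
    return rec
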