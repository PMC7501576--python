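"""Loading EHR extracts, age arithmetic, and assignment-table round trips."""

import datetime as dt

import pandas as pd
import pytest

from pediphen import (
    AlgorithmConfig,
    PatientRecord,
    SyntheticCohortSpec,
    age_on,
    generate_cohort,
    load_cohort,
    read_assignments,
    run_cohort,
    write_assignments,
    write_cohort,
)
from pediphen.ehr_io import SchemaError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.fixture
def tiny_tables(tmp_path):
    patients = _write(
        tmp_path, "patients.csv",
        "patient_id,birth_date,sex,race,ethnicity\n"
        "A,2005-01-10,F,Caucasian,Not Hispanic\n"
        "B,2010-06-01,M,African American,Not Hispanic\n"
        "C,2001-12-31,F,Hispanic,Hispanic\n",
    )
    dx = _write(
        tmp_path, "diagnoses.csv",
        "patient_id,date,code,code_system,setting\n"
        "A,2016-02-01,E10.9,ICD10,outpatient\n"
        "B,2016-03-05,Z00.129,ICD10,outpatient\n"
        "ZZZ,2016-03-05,E11.9,ICD10,inpatient\n",  # orphan row
    )
    labs = _write(
        tmp_path, "labs.csv",
        "patient_id,date,analyte,value,units\n"
        "A,2016-02-01,GLUCOSE,250,mg/dL\n"
        "A,2016-02-01,HBA1C,9.1,%\n"
        "B,2016-03-05,GLUCOSE,5000,mg/dL\n",  # implausible, dropped
    )
    meds = _write(
        tmp_path, "meds.csv",
        "patient_id,date,name,drug_class\n"
        "A,2016-02-20,insulin lispro,INSULIN\n",
    )
    return patients, dx, labs, meds


def test_load_cohort_drops_orphans_and_implausible_labs(tiny_tables, catalog):
    records = load_cohort(*tiny_tables, catalog=catalog)
    by_id = {r.patient_id: r for r in records}
    assert set(by_id) == {"A", "B", "C"}
    assert len(by_id["A"].diagnoses) == 1 and len(by_id["A"].labs) == 2
    assert by_id["B"].labs == []  # the 5000 mg/dL glucose was dropped
    assert by_id["C"].diagnoses == []  # no events at all is fine
    assert by_id["A"].meds[0].drug_class == "INSULIN"


def test_load_cohort_order_insensitive(tiny_tables, catalog, tmp_path):
    records = load_cohort(*tiny_tables, catalog=catalog)
    patients, dx, labs, meds = tiny_tables
    # reverse data rows of every table
    for p in (patients, dx, labs, meds):
        lines = p.read_text().strip().split("\n")
        p.write_text("\n".join([lines[0]] + lines[:0:-1]) + "\n")
    shuffled = load_cohort(patients, dx, labs, meds, catalog=catalog)
    key = lambda r: r.patient_id
    for a, b in zip(sorted(records, key=key), sorted(shuffled, key=key)):
        assert [e.date for e in a.diagnoses] == [e.date for e in b.diagnoses]
        assert [(e.analyte, e.value) for e in a.labs] == [(e.analyte, e.value) for e in b.labs]
        assert [e.name for e in a.meds] == [e.name for e in b.meds]


def test_missing_column_names_the_column(tmp_path, tiny_tables):
    patients, dx, labs, meds = tiny_tables
    bad = _write(tmp_path, "bad_patients.csv", "patient_id,sex,race,ethnicity\nA,F,W,N\n")
    with pytest.raises(SchemaError, match="birth_date"):
        load_cohort(bad, dx, labs, meds)


def test_unparseable_date_reports_line_number(tmp_path, tiny_tables):
    patients, dx, labs, meds = tiny_tables
    bad = _write(
        tmp_path, "bad_dx.csv",
        "patient_id,date,code,code_system,setting\n"
        "A,2016-02-01,E10.9,ICD10,outpatient\n"
        "A,02/03/2016,E10.9,ICD10,outpatient\n",
    )
    with pytest.raises(SchemaError, match="line 3"):
        load_cohort(patients, bad, labs, meds)


@pytest.mark.parametrize(
    "born,index,expected",
    [
        ("2000-01-01", "2016-12-31", 16),
        ("1998-12-31", "2016-12-31", 18),  # birthday today: still eligible
        ("1997-12-30", "2016-12-31", 19),  # one day past the cut
        ("2016-12-31", "2016-12-31", 0),
    ],
)
def test_age_on_completed_years(born, index, expected):
    rec = PatientRecord("p", dt.date.fromisoformat(born), "F", "", "")
    assert age_on(rec, dt.date.fromisoformat(index)) == expected


def test_age_on_rejects_birth_after_index():
    rec = PatientRecord("p", dt.date(2017, 1, 1), "F", "", "")
    with pytest.raises(ValueError):
        age_on(rec, dt.date(2016, 12, 31))


def test_generator_round_trip_preserves_event_streams(tmp_path, catalog):
    """write_cohort then load_cohort reproduces the generated event streams."""
    spec = SyntheticCohortSpec(n_t1dm=15, n_t2dm=15, n_other_dm=5, n_healthy=15, seed=5)
    tables, truth = generate_cohort(spec)
    paths = write_cohort(tables, truth, tmp_path / "cohort")
    records = load_cohort(
        paths["patients"], paths["diagnoses"], paths["labs"], paths["meds"], catalog=catalog
    )
    assert len(records) == 50
    n_dx = sum(len(r.diagnoses) for r in records)
    assert n_dx == len(tables["diagnoses"])
    for rec in records:
        assert all(e.date >= rec.birth_date for e in rec.diagnoses)
        dates = [e.date for e in rec.labs]
        assert dates == sorted(dates)


def test_write_read_write_assignments_idempotent(tmp_path, catalog):
    spec = SyntheticCohortSpec(n_t1dm=10, n_t2dm=10, n_other_dm=0, n_healthy=10, seed=2)
    tables, truth = generate_cohort(spec)
    paths = write_cohort(tables, truth, tmp_path / "c")
    records = load_cohort(
        paths["patients"], paths["diagnoses"], paths["labs"], paths["meds"], catalog=catalog
    )
    assignments, _ = run_cohort(records, AlgorithmConfig(), catalog)
    p1, p2 = tmp_path / "a1.csv", tmp_path / "a2.csv"
    write_assignments(assignments, p1)
    df = read_assignments(p1)
    df.to_csv(p2, index=False)
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_assignments_write_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_assignments([], path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 1 and lines[0].startswith("patient_id,category,version")


def test_read_gold_rejects_unknown_labels(tmp_path):
    from pediphen import read_gold_labels

    p = _write(tmp_path, "gold.csv", "patient_id,reviewed_label\nA,T1DM\nB,MAYBE\n")
    with pytest.raises(ValueError, match="MAYBE"):
        read_gold_labels(p)
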