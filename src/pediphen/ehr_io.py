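"""EHR extract data model and delimited-table I/O.

The tool consumes four comma-delimited tables with header rows:

* ``patients.csv``  — patient_id, birth_date, sex, race, ethnicity
* ``diagnoses.csv`` — patient_id, date, code, code_system, setting
* ``labs.csv``      — patient_id, date, analyte, value, units
* ``meds.csv``      — patient_id, date, name, drug_class

and produces ``assignments.csv`` (one row per patient with the assigned
category, the algorithm version, which criteria fired and the diagnosis-ratio
counts).  Dates are strict ISO-8601; ambiguous formats are rejected rather
than guessed.  Orphan events (rows whose patient_id has no patients.csv row)
are reported and dropped.  Lab values outside plausibility bounds (glucose
1–2000 mg/dL, HbA1c 2–20 %) are dropped with a warning rather than used.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codesets import CodeCatalog, drug_class_of

logger = logging.getLogger(__name__)

GLUCOSE_BOUNDS = (1.0, 2000.0)
HBA1C_BOUNDS = (2.0, 20.0)

ASSIGNMENT_COLUMNS = [
    "patient_id",
    "category",
    "version",
    "age_ineligible",
    "t1_insulin90",
    "t1_glucose",
    "t1_hba1c",
    "t2_dx",
    "t2_metformin",
    "other_dm",
    "t1_code_count",
    "t2_code_count",
]


class SchemaError(ValueError):
    """An input table is missing a required column or has an unparseable row."""


@dataclass(frozen=True)
class DxEvent:
    date: dt.date
    code: str
    code_system: str  # ICD9 | ICD10
    setting: str  # inpatient | outpatient
    source_line: int = -1  # 1-based line in the source file, for audit logs


@dataclass(frozen=True)
class LabEvent:
    date: dt.date
    analyte: str  # GLUCOSE | HBA1C | OTHER
    value: float  # GLUCOSE in mg/dL, HBA1C in percent
    source_line: int = -1


@dataclass(frozen=True)
class MedEvent:
    date: dt.date
    drug_class: str  # INSULIN | METFORMIN | OTHER, derived from name
    name: str
    source_line: int = -1


@dataclass
class PatientRecord:
    """One patient's demographics plus date-sorted event streams."""

    patient_id: str
    birth_date: dt.date
    sex: str
    race: str
    ethnicity: str
    diagnoses: list[DxEvent] = field(default_factory=list)
    labs: list[LabEvent] = field(default_factory=list)
    meds: list[MedEvent] = field(default_factory=list)

    def sort_events(self) -> None:
        # canonical content-based order so loading is input-order-insensitive
        self.diagnoses.sort(key=lambda e: (e.date, e.code, e.setting))
        self.labs.sort(key=lambda e: (e.date, e.analyte, e.value))
        self.meds.sort(key=lambda e: (e.date, e.name, e.drug_class))


def age_on(patient: PatientRecord, index_date: dt.date) -> int:
    """Completed years of age on ``index_date`` (birthday not reached yet
    subtracts one).  The eligibility rule is age <= 18 on the index date."""
    born = patient.birth_date
    if born > index_date:
        raise ValueError(
            f"patient {patient.patient_id}: birth date {born} after index date {index_date}"
        )
    age = index_date.year - born.year
    if (index_date.month, index_date.day) < (born.month, born.day):
        age -= 1
    return age


def _parse_iso_date(value: str, table: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise SchemaError(f"{table} line {line}: unparseable date {value!r} (expected YYYY-MM-DD)") from exc


def _read_table(path: str | Path, required: list[str], table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")
    # line numbers: header is line 1, first data row is line 2
    df = df.reset_index(drop=True)
    return df


def load_cohort(
    patients_path: str | Path,
    dx_path: str | Path,
    labs_path: str | Path,
    meds_path: str | Path,
    catalog: CodeCatalog | None = None,
) -> list[PatientRecord]:
    """Load the four EHR tables into one :class:`PatientRecord` per patient.

    Orphan events are dropped (counts logged); event streams come back sorted
    ascending by date, so loading is insensitive to input row order.  When a
    catalog is given the med drug_class column is re-derived from the name so
    class membership is deterministic regardless of what the file claims.
    """
    pat_df = _read_table(patients_path, ["patient_id", "birth_date", "sex", "race", "ethnicity"], "patients")
    records: dict[str, PatientRecord] = {}
    for row in pat_df.itertuples(index=True):
        line = row.Index + 2
        birth = _parse_iso_date(row.birth_date, "patients", line)
        pid = str(row.patient_id)
        if pid in records:
            raise SchemaError(f"patients: duplicate patient_id {pid!r}")
        records[pid] = PatientRecord(
            patient_id=pid, birth_date=birth, sex=row.sex, race=row.race, ethnicity=row.ethnicity
        )

    orphans = {"diagnoses": 0, "labs": 0, "meds": 0}

    dx_df = _read_table(dx_path, ["patient_id", "date", "code", "code_system", "setting"], "diagnoses")
    for row in dx_df.itertuples(index=True):
        line = row.Index + 2
        rec = records.get(str(row.patient_id))
        if rec is None:
            orphans["diagnoses"] += 1
            continue
        if not str(row.code).strip():
            raise SchemaError(f"diagnoses line {line}: empty code")
        setting = str(row.setting).strip().lower()
        if setting not in ("inpatient", "outpatient"):
            raise SchemaError(f"diagnoses line {line}: bad setting {row.setting!r}")
        rec.diagnoses.append(
            DxEvent(
                date=_parse_iso_date(row.date, "diagnoses", line),
                code=str(row.code).strip().upper(),
                code_system=str(row.code_system).strip().upper(),
                setting=setting,
                source_line=int(line),
            )
        )

    labs_df = _read_table(labs_path, ["patient_id", "date", "analyte", "value"], "labs")
    n_dropped_labs = 0
    for row in labs_df.itertuples(index=True):
        line = row.Index + 2
        rec = records.get(str(row.patient_id))
        if rec is None:
            orphans["labs"] += 1
            continue
        analyte = str(row.analyte).strip().upper()
        if analyte not in ("GLUCOSE", "HBA1C"):
            analyte = "OTHER"
        try:
            value = float(row.value)
        except ValueError as exc:
            raise SchemaError(f"labs line {line}: unparseable value {row.value!r}") from exc
        units = str(getattr(row, "units", "")).strip()
        if not units and analyte in ("GLUCOSE", "HBA1C"):
            logger.warning(
                "labs line %d: missing units for %s, assuming %s",
                line, analyte, "mg/dL" if analyte == "GLUCOSE" else "percent",
            )
        bounds = GLUCOSE_BOUNDS if analyte == "GLUCOSE" else HBA1C_BOUNDS if analyte == "HBA1C" else None
        if value <= 0 or (bounds and not (bounds[0] <= value <= bounds[1])):
            logger.warning("labs line %d: %s value %s outside plausibility bounds, dropped", line, analyte, value)
            n_dropped_labs += 1
            continue
        rec.labs.append(
            LabEvent(date=_parse_iso_date(row.date, "labs", line), analyte=analyte, value=value, source_line=int(line))
        )

    meds_df = _read_table(meds_path, ["patient_id", "date", "name"], "meds")
    for row in meds_df.itertuples(index=True):
        line = row.Index + 2
        rec = records.get(str(row.patient_id))
        if rec is None:
            orphans["meds"] += 1
            continue
        name = str(row.name).strip()
        if catalog is not None:
            drug_class = drug_class_of(name, catalog)
        else:
            drug_class = str(getattr(row, "drug_class", "OTHER")).strip().upper() or "OTHER"
        rec.meds.append(
            MedEvent(date=_parse_iso_date(row.date, "meds", line), drug_class=drug_class, name=name, source_line=int(line))
        )

    for rec in records.values():
        for ev in rec.diagnoses + rec.labs + rec.meds:  # type: ignore[operator]
            if ev.date < rec.birth_date:
                raise SchemaError(
                    f"patient {rec.patient_id}: event on {ev.date} precedes birth date {rec.birth_date}"
                )
        rec.sort_events()

    total_orphans = sum(orphans.values())
    if total_orphans:
        logger.warning("dropped orphan events with no matching patient: %s", orphans)
    logger.info(
        "loaded %d patients, %d dx, %d labs (%d dropped), %d meds, %d orphans",
        len(records), sum(len(r.diagnoses) for r in records.values()),
        sum(len(r.labs) for r in records.values()), n_dropped_labs,
        sum(len(r.meds) for r in records.values()), total_orphans,
    )
    return list(records.values())


def assignments_to_frame(assignments) -> pd.DataFrame:
    """Render PhenotypeAssignments as a stable-column DataFrame."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "patient_id": a.patient_id,
                "category": a.category.value,
                "version": a.version.value,
                "age_ineligible": a.age_ineligible,
                "t1_insulin90": a.criteria_fired.t1_insulin90,
                "t1_glucose": a.criteria_fired.t1_glucose,
                "t1_hba1c": a.criteria_fired.t1_hba1c,
                "t2_dx": a.criteria_fired.t2_dx,
                "t2_metformin": a.criteria_fired.t2_metformin,
                "other_dm": a.criteria_fired.other_dm,
                "t1_code_count": a.ratio.t1_count,
                "t2_code_count": a.ratio.t2_count,
            }
        )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def write_assignments(assignments, path: str | Path) -> None:
    """Write assignments deterministically (stable column order, one row per
    patient; an empty list yields a header-only file)."""
    df = assignments_to_frame(assignments)
    df.to_csv(path, index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read an assignments table back, normalizing boolean flags."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assignments: missing columns {missing}")
    for col in ("age_ineligible", "t1_insulin90", "t1_glucose", "t1_hba1c", "t2_dx", "t2_metformin", "other_dm"):
        df[col] = df[col].astype(bool)
    return df[ASSIGNMENT_COLUMNS]


def read_gold_labels(path: str | Path) -> pd.DataFrame:
    """Read a gold-standard label table (patient_id, reviewed_label)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("patient_id", "reviewed_label"):
        if col not in df.columns:
            raise SchemaError(f"gold labels: missing required column {col!r}")
    allowed = {"T1DM", "T2DM", "OTHER_DM", "NO_DX"}
    bad = sorted(set(df["reviewed_label"]) - allowed)
    if bad:
        raise ValueError(f"gold labels outside {sorted(allowed)}: {bad}")
    return df[["patient_id", "reviewed_label"]]
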