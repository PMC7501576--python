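"""The computable phenotype: rule application and cohort-level summaries.

A patient aged <= 18 on the index date qualifies as T1DM when they carry a
T1DM diagnosis code and at least one of three supporting criteria holds:

1. an insulin order within the medication window (default 90 days) of a
   T1DM-coded diagnosis event,
2. a glucose result above the threshold (default > 200 mg/dL), or
3. an HbA1c result above the threshold (default > 6.5 %).

T2DM qualification is by diagnosis code alone under versions v1/v2; version
v3 additionally requires a metformin prescription.  Patients carrying an
other-diabetes code (secondary DM, MODY, neonatal DM — the neonatal code is
P61.0 under v1 and P70.2 under v2/v3) are carved into a separate OTHER_DM
category before the T1/T2 decision.  Conflicting T1/T2 coding is resolved by
the diagnosis ratio: the type with strictly more code occurrences wins;
equal nonzero counts with both type criteria satisfied are INDETERMINATE and
are excluded from validation denominators.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, replace

import pandas as pd

from .codesets import AlgorithmVersion, CodeCatalog, DxCategory, classify_dx_code
from .ehr_io import PatientRecord, age_on

DEFAULT_INDEX_DATE = dt.date(2016, 12, 31)
AGE_BANDS = ((0, 5), (6, 10), (11, 15), (16, 18))


class Category(str, enum.Enum):
    """Final phenotype assignment for one patient."""

    T1DM = "T1DM"
    T2DM = "T2DM"
    OTHER_DM = "OTHER_DM"
    NO_DX = "NO_DX"
    INDETERMINATE = "INDETERMINATE"


class Majority(str, enum.Enum):
    T1DM = "T1DM"
    T2DM = "T2DM"
    TIE = "TIE"
    NONE = "NONE"


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the phenotype.

    ``threshold_strict`` selects ">" (default) versus ">=" lab comparisons;
    ``insulin_window_days`` is a symmetric window around each T1DM-coded
    diagnosis event.  ``ratio_counting`` counts diagnosis code instances
    ("events", default) or distinct diagnosis dates ("encounters").
    """

    version: AlgorithmVersion = AlgorithmVersion.V3
    index_date: dt.date = DEFAULT_INDEX_DATE
    insulin_window_days: int = 90
    glucose_threshold_mgdl: float = 200.0
    hba1c_threshold_pct: float = 6.5
    threshold_strict: bool = True
    ratio_counting: str = "events"  # "events" | "encounters"

    def __post_init__(self) -> None:
        if self.insulin_window_days <= 0:
            raise ValueError("insulin_window_days must be positive")
        if self.glucose_threshold_mgdl <= 0 or self.hba1c_threshold_pct <= 0:
            raise ValueError("lab thresholds must be positive")
        if self.ratio_counting not in ("events", "encounters"):
            raise ValueError("ratio_counting must be 'events' or 'encounters'")


@dataclass(frozen=True)
class DiagnosisRatio:
    """T1DM vs T2DM code-occurrence counts and the resulting majority."""

    t1_count: int
    t2_count: int

    @property
    def majority(self) -> Majority:
        if self.t1_count == self.t2_count == 0:
            return Majority.NONE
        if self.t1_count == self.t2_count:
            return Majority.TIE
        return Majority.T1DM if self.t1_count > self.t2_count else Majority.T2DM


@dataclass(frozen=True)
class CriteriaFlags:
    t1_insulin90: bool = False
    t1_glucose: bool = False
    t1_hba1c: bool = False
    t2_dx: bool = False
    t2_metformin: bool = False
    other_dm: bool = False


@dataclass(frozen=True)
class PhenotypeAssignment:
    patient_id: str
    category: Category
    version: AlgorithmVersion
    criteria_fired: CriteriaFlags
    ratio: DiagnosisRatio
    age_ineligible: bool = False


def compute_diagnosis_ratio(
    patient: PatientRecord, catalog: CodeCatalog, version: AlgorithmVersion,
    counting: str = "events",
) -> DiagnosisRatio:
    """Count T1DM- and T2DM-classified diagnosis occurrences for one patient."""
    t1_keys, t2_keys = [], []
    for ev in patient.diagnoses:
        cat = classify_dx_code(ev.code, catalog, version)
        if cat is DxCategory.T1DM:
            t1_keys.append(ev.date)
        elif cat is DxCategory.T2DM:
            t2_keys.append(ev.date)
    if counting == "encounters":
        return DiagnosisRatio(t1_count=len(set(t1_keys)), t2_count=len(set(t2_keys)))
    return DiagnosisRatio(t1_count=len(t1_keys), t2_count=len(t2_keys))


def _exceeds(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


def t1dm_criteria(
    patient: PatientRecord, config: AlgorithmConfig, catalog: CodeCatalog
) -> CriteriaFlags:
    """Evaluate the three disjunctive T1DM supporting criteria.

    All three require at least one T1DM-coded diagnosis event; without one,
    every flag is False.  The insulin criterion is met when any INSULIN order
    falls within ± ``insulin_window_days`` of any T1DM-coded event.
    """
    t1_dates = [
        ev.date for ev in patient.diagnoses
        if classify_dx_code(ev.code, catalog, config.version) is DxCategory.T1DM
    ]
    if not t1_dates:
        return CriteriaFlags()
    window = dt.timedelta(days=config.insulin_window_days)
    insulin = any(
        abs(med.date - d) <= window
        for med in patient.meds if med.drug_class == "INSULIN"
        for d in t1_dates
    )
    glucose = any(
        _exceeds(lab.value, config.glucose_threshold_mgdl, config.threshold_strict)
        for lab in patient.labs if lab.analyte == "GLUCOSE"
    )
    hba1c = any(
        _exceeds(lab.value, config.hba1c_threshold_pct, config.threshold_strict)
        for lab in patient.labs if lab.analyte == "HBA1C"
    )
    return CriteriaFlags(t1_insulin90=insulin, t1_glucose=glucose, t1_hba1c=hba1c)


def t2dm_criteria(
    patient: PatientRecord, config: AlgorithmConfig, catalog: CodeCatalog
) -> CriteriaFlags:
    """Evaluate T2DM qualification inputs: a T2DM code, and (for v3) metformin."""
    t2_dx = any(
        classify_dx_code(ev.code, catalog, config.version) is DxCategory.T2DM
        for ev in patient.diagnoses
    )
    metformin = any(med.drug_class == "METFORMIN" for med in patient.meds)
    return CriteriaFlags(t2_dx=t2_dx, t2_metformin=metformin)


def _t1_qualified(flags: CriteriaFlags) -> bool:
    return flags.t1_insulin90 or flags.t1_glucose or flags.t1_hba1c


def _t2_qualified(flags: CriteriaFlags, version: AlgorithmVersion) -> bool:
    if version is AlgorithmVersion.V3:
        return flags.t2_dx and flags.t2_metformin
    return flags.t2_dx


def assign_phenotype(
    patient: PatientRecord, config: AlgorithmConfig, catalog: CodeCatalog
) -> PhenotypeAssignment:
    """Apply the full decision procedure to one patient.

    Order: age eligibility, then the other-DM carve-out, then the diagnosis
    ratio with type-specific qualification.  Criteria flags and the ratio are
    always populated for audit, even for ineligible or other-DM patients.
    """
    ratio = compute_diagnosis_ratio(patient, catalog, config.version, config.ratio_counting)
    t1_flags = t1dm_criteria(patient, config, catalog)
    t2_flags = t2dm_criteria(patient, config, catalog)
    other = any(
        classify_dx_code(ev.code, catalog, config.version) is DxCategory.OTHER_DM
        for ev in patient.diagnoses
    )
    flags = replace(
        t1_flags, t2_dx=t2_flags.t2_dx, t2_metformin=t2_flags.t2_metformin, other_dm=other
    )

    age = age_on(patient, config.index_date)
    if age > 18:
        return PhenotypeAssignment(
            patient.patient_id, Category.NO_DX, config.version, flags, ratio, age_ineligible=True
        )
    if other:
        return PhenotypeAssignment(patient.patient_id, Category.OTHER_DM, config.version, flags, ratio)

    t1_ok = _t1_qualified(flags)
    t2_ok = _t2_qualified(flags, config.version)
    majority = ratio.majority
    if majority is Majority.TIE and t1_ok and t2_ok:
        category = Category.INDETERMINATE
    elif majority is Majority.T1DM and t1_ok:
        category = Category.T1DM
    elif majority is Majority.T2DM and t2_ok:
        category = Category.T2DM
    else:
        category = Category.NO_DX
    return PhenotypeAssignment(patient.patient_id, category, config.version, flags, ratio)


@dataclass
class CohortSummary:
    """Category counts plus per-category demographic breakdowns."""

    counts: dict[str, int]
    breakdown: pd.DataFrame  # rows: category x (sex | race | age band | insulin)

    def __str__(self) -> str:
        parts = [f"{k}={v}" for k, v in self.counts.items()]
        return "counts: " + ", ".join(parts)


def _age_band(age: int) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return ">18"


def summarize_cohort(
    records: list[PatientRecord],
    assignments: list[PhenotypeAssignment],
    config: AlgorithmConfig,
) -> CohortSummary:
    """Tabulate counts per category and breakdowns by sex, race, age band
    and insulin exposure (the layout of the published cohort table)."""
    by_id = {r.patient_id: r for r in records}
    counts = {c.value: 0 for c in Category}
    rows = []
    for a in assignments:
        counts[a.category.value] += 1
        rec = by_id[a.patient_id]
        rows.append(
            {
                "category": a.category.value,
                "sex": rec.sex,
                "race": rec.race,
                "age_band": _age_band(age_on(rec, config.index_date)),
                "on_insulin": any(m.drug_class == "INSULIN" for m in rec.meds),
            }
        )
    df = pd.DataFrame(rows, columns=["category", "sex", "race", "age_band", "on_insulin"])
    pieces = []
    for dim in ("sex", "race", "age_band", "on_insulin"):
        tab = (
            df.groupby(["category", dim], observed=True).size().reset_index(name="n")
            .rename(columns={dim: "level"})
        )
        tab.insert(1, "dimension", dim)
        tab["level"] = tab["level"].astype(str)
        pieces.append(tab)
    breakdown = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["category", "dimension", "level", "n"]
    )
    return CohortSummary(counts=counts, breakdown=breakdown)


def run_cohort(
    records: list[PatientRecord], config: AlgorithmConfig, catalog: CodeCatalog
) -> tuple[list[PhenotypeAssignment], CohortSummary]:
    """Assign every patient independently and summarize the cohort."""
    if not records:
        raise ValueError("empty cohort")
    assignments = [assign_phenotype(r, config, catalog) for r in records]
    summary = summarize_cohort(records, assignments, config)
    return assignments, summary
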