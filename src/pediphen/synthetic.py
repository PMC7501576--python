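"""Seeded synthetic pediatric EHR cohorts with known true diabetes status.

The generator emulates the features of real extracts that the phenotype
rules have to survive: conflicting T1DM/T2DM coding across encounters
(``conflict_rate``), exactly tied code counts (``tie_rate``), group-specific
glucose and HbA1c distributions (truncated normals whose means, SDs and
truncation ranges default to the development cohort's observed summaries),
insulin and metformin prescribing with configurable coverage, missing labs,
and other-DM coding (other-specified / secondary / neonatal).  Every patient
carries a known true category in the emitted truth table, so engine output
can be scored against truth exactly.

It does not attempt realistic longitudinal care trajectories: each patient
gets a handful of diagnosis events in a single index year and at most one
glucose and one HbA1c result (a most-recent-value reading of the summary
statistics it is parameterized from).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import DEFAULT_INDEX_DATE, AlgorithmConfig

__all__ = [
    "LabDist",
    "GroupProfile",
    "SyntheticCohortSpec",
    "generate_cohort",
    "write_cohort",
    "expected_t1_sensitivity",
    "paper_review_fixture",
]


@dataclass(frozen=True)
class LabDist:
    """Truncated-normal lab distribution (mean/SD with plausibility range)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.lower >= self.upper:
            raise ValueError("bad lab distribution parameters")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        dist = self._frozen()
        return dist.ppf(rng.uniform(size=size))

    def prob_above(self, threshold: float) -> float:
        """P(value > threshold) under the truncated normal."""
        return float(self._frozen().sf(threshold))


@dataclass(frozen=True)
class GroupProfile:
    """Demographic and lab profile for one true-status group."""

    glucose: LabDist
    hba1c: LabDist
    age_mean: float
    age_sd: float
    female_prob: float
    hispanic_prob: float
    race_probs: dict[str, float]


def _default_groups() -> dict[str, GroupProfile]:
    # Glucose in mg/dL, HbA1c in percent; development-cohort summaries.
    races = ("Caucasian", "African American", "Hispanic", "Other")
    return {
        "NO_DX": GroupProfile(
            glucose=LabDist(89.43, 30.33, 7, 284),
            hba1c=LabDist(5.48, 0.58, 4.8, 7.5),
            age_mean=7.8, age_sd=5.56, female_prob=0.523, hispanic_prob=0.098,
            race_probs=dict(zip(races, (0.60, 0.25, 0.08, 0.07))),
        ),
        "T1DM": GroupProfile(
            glucose=LabDist(207.59, 98.57, 58, 555),
            hba1c=LabDist(9.27, 1.80, 5.6, 14.0),
            age_mean=12.3, age_sd=4.07, female_prob=0.531, hispanic_prob=0.18,
            race_probs=dict(zip(races, (0.68, 0.08, 0.15, 0.09))),
        ),
        "T2DM": GroupProfile(
            glucose=LabDist(161.11, 96.83, 64, 432),
            hba1c=LabDist(7.92, 2.90, 4.9, 14.0),
            age_mean=15.4, age_sd=2.87, female_prob=0.686, hispanic_prob=0.057,
            race_probs=dict(zip(races, (0.37, 0.54, 0.03, 0.06))),
        ),
        # other DM skews very young (neonatal forms dominate)
        "OTHER_DM": GroupProfile(
            glucose=LabDist(161.11, 96.83, 64, 432),
            hba1c=LabDist(7.92, 2.90, 4.9, 14.0),
            age_mean=4.0, age_sd=4.0, female_prob=0.5, hispanic_prob=0.10,
            race_probs=dict(zip(races, (0.30, 0.35, 0.10, 0.25))),
        ),
    }


T1_CODES = ("E10.9", "E10.65", "E10.10")
T2_CODES = ("E11.9", "E11.65", "E11.8")
OTHER_CODES = ("E13.9", "E08.9", "E09.9")
NEONATAL_CODE = "P70.2"
WELL_CHILD_CODES = ("Z00.129", "Z00.121", "J06.9", "H66.90")
INSULIN_NAMES = ("insulin glargine", "insulin lispro", "insulin aspart")
METFORMIN_NAME = "metformin hydrochloride 500 mg"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generator parameters.

    ``conflict_rate`` is the probability a diabetic patient accrues at least
    one opposite-type code while keeping a strict majority of the true type;
    ``tie_rate`` forces exactly tied counts instead.  ``neonatal_frac`` is
    the share of other-DM patients coded with the neonatal code P70.2
    (which the v1 other-DM set does not recognize) rather than an
    other-specified/secondary code.
    """

    n_t1dm: int = 100
    n_t2dm: int = 100
    n_other_dm: int = 0
    n_healthy: int = 100
    conflict_rate: float = 0.2
    tie_rate: float = 0.025
    insulin_prob_t1: float = 0.92
    metformin_prob_t2: float = 0.9
    insulin_prob_t2: float = 0.5
    insulin_prob_other: float = 0.1
    missing_lab_rate: float = 0.1
    neonatal_frac: float = 0.25
    index_date: dt.date = DEFAULT_INDEX_DATE
    insulin_window_days: int = 90
    seed: int = 0
    groups: dict[str, GroupProfile] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        for name in ("n_t1dm", "n_t2dm", "n_other_dm", "n_healthy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_t1dm + self.n_t2dm + self.n_other_dm + self.n_healthy == 0:
            raise ValueError("cohort must contain at least one patient")
        for name in (
            "conflict_rate", "tie_rate", "insulin_prob_t1", "metformin_prob_t2",
            "insulin_prob_t2", "insulin_prob_other", "missing_lab_rate", "neonatal_frac",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.conflict_rate + self.tie_rate > 1.0:
            raise ValueError("conflict_rate + tie_rate must not exceed 1")
        if self.insulin_window_days <= 0:
            raise ValueError("insulin_window_days must be positive")


def _sample_age(rng: np.random.Generator, profile: GroupProfile) -> int:
    a = (0 - profile.age_mean) / profile.age_sd
    b = (18.999 - profile.age_mean) / profile.age_sd
    age = stats.truncnorm(a, b, loc=profile.age_mean, scale=profile.age_sd).ppf(rng.uniform())
    return int(age)


def _birth_date(rng: np.random.Generator, age: int, index_date: dt.date) -> dt.date:
    anchor_year = index_date.year - age
    month, day = index_date.month, index_date.day
    try:
        anchor = dt.date(anchor_year, month, day)
    except ValueError:  # Feb 29 anchor in a non-leap year
        anchor = dt.date(anchor_year, 2, 28)
    return anchor - dt.timedelta(days=int(rng.integers(0, 364)))


def _event_date(rng: np.random.Generator, birth: dt.date, index_date: dt.date) -> dt.date:
    start = max(birth, dt.date(index_date.year, 1, 1))
    span = (index_date - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the four EHR tables plus a truth table, deterministically.

    Returns ``(tables, truth)`` where tables maps ``patients`` / ``diagnoses``
    / ``labs`` / ``meds`` to DataFrames in the standard column layout and
    truth has columns patient_id, true_category.
    """
    rng = np.random.default_rng(spec.seed)
    window = spec.insulin_window_days
    patients, dx_rows, lab_rows, med_rows, truth_rows = [], [], [], [], []

    plan = (
        [("T1DM", None)] * spec.n_t1dm
        + [("T2DM", None)] * spec.n_t2dm
        + [("OTHER_DM", None)] * spec.n_other_dm
        + [("NO_DX", None)] * spec.n_healthy
    )
    for i, (group, _) in enumerate(plan):
        pid = f"P{i + 1:05d}"
        profile = spec.groups[group]
        age = _sample_age(rng, profile)
        birth = _birth_date(rng, age, spec.index_date)
        sex = "F" if rng.uniform() < profile.female_prob else "M"
        races, rprobs = zip(*profile.race_probs.items())
        race = str(rng.choice(races, p=np.asarray(rprobs) / np.sum(rprobs)))
        ethnicity = "Hispanic" if rng.uniform() < profile.hispanic_prob else "Not Hispanic"
        patients.append(
            {"patient_id": pid, "birth_date": birth.isoformat(), "sex": sex,
             "race": race, "ethnicity": ethnicity}
        )
        truth_rows.append({"patient_id": pid, "true_category": group})

        dx_dates: list[dt.date] = []
        opp_dates: list[dt.date] = []
        tied = False
        if group in ("T1DM", "T2DM"):
            own_codes = T1_CODES if group == "T1DM" else T2_CODES
            opp_codes = T2_CODES if group == "T1DM" else T1_CODES
            n_own = int(rng.integers(2, 6))
            u = rng.uniform()
            if u < spec.tie_rate:
                n_opp, tied = n_own, True
            elif u < spec.tie_rate + spec.conflict_rate:
                n_opp = int(rng.integers(1, n_own))
            else:
                n_opp = 0
            for _ in range(n_own):
                d = _event_date(rng, birth, spec.index_date)
                dx_dates.append(d)
                dx_rows.append(_dx_row(pid, d, str(rng.choice(own_codes)), rng))
            for _ in range(n_opp):
                d = _event_date(rng, birth, spec.index_date)
                opp_dates.append(d)
                dx_rows.append(_dx_row(pid, d, str(rng.choice(opp_codes)), rng))
        elif group == "OTHER_DM":
            code = NEONATAL_CODE if rng.uniform() < spec.neonatal_frac else str(rng.choice(OTHER_CODES))
            d = _event_date(rng, birth, spec.index_date)
            dx_dates.append(d)
            dx_rows.append(_dx_row(pid, d, code, rng))
        else:
            for _ in range(int(rng.integers(1, 4))):
                d = _event_date(rng, birth, spec.index_date)
                dx_rows.append(_dx_row(pid, d, str(rng.choice(WELL_CHILD_CODES)), rng))

        # labs: at most one glucose and one HbA1c, group-distributed
        for analyte, dist, fmt in (
            ("GLUCOSE", profile.glucose, "{:.1f}"),
            ("HBA1C", profile.hba1c, "{:.2f}"),
        ):
            value = float(dist.sample(rng, 1)[0])
            missing = rng.uniform() < spec.missing_lab_rate
            if not missing:
                lab_rows.append(
                    {"patient_id": pid, "date": _event_date(rng, birth, spec.index_date).isoformat(),
                     "analyte": analyte, "value": fmt.format(value),
                     "units": "mg/dL" if analyte == "GLUCOSE" else "%"}
                )

        # medications; a tied (genuinely conflicting) patient shows mixed
        # treatment: insulin anchored to a T1-coded encounter plus metformin
        t1_anchor_dates = dx_dates if group == "T1DM" else opp_dates
        if group == "T1DM" or (group == "T2DM" and tied):
            if rng.uniform() < spec.insulin_prob_t1:
                anchor = t1_anchor_dates[int(rng.integers(0, len(t1_anchor_dates)))]
                offset = int(rng.integers(-window, window + 1))
                med_date = max(birth, anchor + dt.timedelta(days=offset))
                med_rows.append(_med_row(pid, med_date, str(rng.choice(INSULIN_NAMES)), "INSULIN"))
        if group == "T2DM" or (group == "T1DM" and tied):
            if rng.uniform() < spec.metformin_prob_t2:
                med_rows.append(
                    _med_row(pid, _event_date(rng, birth, spec.index_date), METFORMIN_NAME, "METFORMIN")
                )
        if group == "T2DM" and not tied and rng.uniform() < spec.insulin_prob_t2:
            med_rows.append(
                _med_row(pid, _event_date(rng, birth, spec.index_date),
                         str(rng.choice(INSULIN_NAMES)), "INSULIN")
            )
        if group == "OTHER_DM" and rng.uniform() < spec.insulin_prob_other:
            anchor = dx_dates[0]
            med_date = max(birth, anchor + dt.timedelta(days=int(rng.integers(-window, window + 1))))
            med_rows.append(_med_row(pid, med_date, str(rng.choice(INSULIN_NAMES)), "INSULIN"))

    tables = {
        "patients": pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex", "race", "ethnicity"]),
        "diagnoses": pd.DataFrame(dx_rows, columns=["patient_id", "date", "code", "code_system", "setting"]),
        "labs": pd.DataFrame(lab_rows, columns=["patient_id", "date", "analyte", "value", "units"]),
        "meds": pd.DataFrame(med_rows, columns=["patient_id", "date", "name", "drug_class"]),
    }
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "true_category"])
    return tables, truth


def _dx_row(pid: str, date: dt.date, code: str, rng: np.random.Generator) -> dict:
    return {
        "patient_id": pid, "date": date.isoformat(), "code": code,
        "code_system": "ICD10",
        "setting": "inpatient" if rng.uniform() < 0.3 else "outpatient",
    }


def _med_row(pid: str, date: dt.date, name: str, drug_class: str) -> dict:
    return {"patient_id": pid, "date": date.isoformat(), "name": name, "drug_class": drug_class}


def write_cohort(
    tables: dict[str, pd.DataFrame], truth: pd.DataFrame, out_dir
) -> dict[str, str]:
    """Write the four tables plus truth.csv under ``out_dir``; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in {**tables, "truth": truth}.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def expected_t1_sensitivity(spec: SyntheticCohortSpec, config: AlgorithmConfig) -> float:
    """Closed-form detection probability for a generated T1DM patient.

    A T1DM patient with an untied code majority is classified T1DM iff at
    least one supporting criterion fires; the generator makes the three
    evidence channels independent, so

        p = 1 - (1 - p_ins) (1 - p_glu) (1 - p_a1c)

    with p_ins the insulin-coverage probability (orders are always placed
    inside the window) and p_glu / p_a1c the product of lab availability and
    the truncated-normal exceedance probability of the threshold.  Valid for
    tie_rate = 0; ties are INDETERMINATE, not false negatives.
    """
    g = spec.groups["T1DM"]
    avail = 1.0 - spec.missing_lab_rate
    p_glu = avail * g.glucose.prob_above(config.glucose_threshold_mgdl)
    p_a1c = avail * g.hba1c.prob_above(config.hba1c_threshold_pct)
    p_ins = spec.insulin_prob_t1
    return 1.0 - (1.0 - p_ins) * (1.0 - p_glu) * (1.0 - p_a1c)


# ---------------------------------------------------------------------------
# Chart-review fixture
# ---------------------------------------------------------------------------

# (assigned, gold, n): joint allocation of the 295 reviewed records.  Cells
# are pinned by the published confusion counts — T1DM (tp 124, fp 7 split 5
# no-diagnosis / 2 T2DM, fn 4, tn 160) and T2DM (tp 33, fp 31, fn 2, tn 229)
# — together with the assigned marginals 131/64/100 and the review marginals
# 128/35/132.  The 4 T1DM false negatives are carried as assigned-NO_DX.
_FIXTURE_CELLS = (
    ("T1DM", "T1DM", 124),
    ("T1DM", "T2DM", 2),
    ("T1DM", "NO_DX", 5),
    ("T2DM", "T2DM", 33),
    ("T2DM", "NO_DX", 31),
    ("NO_DX", "T1DM", 4),
    ("NO_DX", "NO_DX", 96),
)


def paper_review_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The 295-record labeled validation fixture, by direct count allocation.

    Returns ``(assignments, gold)``: an assignments frame in the standard
    column layout whose cross-tabulation against the gold labels reproduces
    both published confusion matrices simultaneously, and the gold table.
    No sampling is involved; the allocation is exact integer bookkeeping.
    """
    from .ehr_io import ASSIGNMENT_COLUMNS

    assign_rows, gold_rows = [], []
    i = 0
    for assigned, gold, n in _FIXTURE_CELLS:
        for _ in range(n):
            i += 1
            pid = f"R{i:04d}"
            assign_rows.append(
                {
                    "patient_id": pid,
                    "category": assigned,
                    "version": "v1",
                    "age_ineligible": False,
                    "t1_insulin90": assigned == "T1DM",
                    "t1_glucose": False,
                    "t1_hba1c": False,
                    "t2_dx": assigned == "T2DM",
                    "t2_metformin": False,
                    "other_dm": False,
                    "t1_code_count": 3 if assigned == "T1DM" else 0,
                    "t2_code_count": 2 if assigned == "T2DM" else 0,
                }
            )
            gold_rows.append({"patient_id": pid, "reviewed_label": gold})
    assignments = pd.DataFrame(assign_rows, columns=ASSIGNMENT_COLUMNS)
    gold = pd.DataFrame(gold_rows, columns=["patient_id", "reviewed_label"])
    return assignments, gold
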