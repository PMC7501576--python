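"""Phenotype rules: diagnosis ratio, supporting criteria, decision order."""

import datetime as dt

import pytest

from pediphen import (
    AlgorithmConfig,
    AlgorithmVersion,
    Category,
    assign_phenotype,
    compute_diagnosis_ratio,
    run_cohort,
    t1dm_criteria,
    t2dm_criteria,
)
from pediphen.engine import Majority

from conftest import make_patient

V1, V2, V3 = AlgorithmVersion.V1, AlgorithmVersion.V2, AlgorithmVersion.V3


@pytest.mark.parametrize(
    "t1,t2,majority",
    [(3, 1, Majority.T1DM), (1, 3, Majority.T2DM), (2, 2, Majority.TIE), (0, 0, Majority.NONE)],
)
def test_diagnosis_ratio_majority(catalog, t1, t2, majority):
    patient = make_patient(t1_codes=t1, t2_codes=t2)
    ratio = compute_diagnosis_ratio(patient, catalog, V1)
    assert (ratio.t1_count, ratio.t2_count, ratio.majority) == (t1, t2, majority)


def test_encounter_counting_dedupes_same_day_codes(catalog):
    patient = make_patient(t1_codes=1, extra_dx=("E10.65", "E10.10"))  # 3 T1 codes, same day
    events = compute_diagnosis_ratio(patient, catalog, V1, counting="events")
    encounters = compute_diagnosis_ratio(patient, catalog, V1, counting="encounters")
    assert events.t1_count == 3 and encounters.t1_count == 1


@pytest.mark.parametrize(
    "offset,expected", [(45, True), (-45, True), (90, True), (91, False), (120, False)]
)
def test_insulin_window_is_symmetric_90_days(catalog, offset, expected):
    patient = make_patient(t1_codes=1, insulin_offset_days=offset)
    flags = t1dm_criteria(patient, AlgorithmConfig(), catalog)
    assert flags.t1_insulin90 is expected


@pytest.mark.parametrize(
    "glucose,hba1c,strict,glu_fires,a1c_fires",
    [
        (201.0, 6.6, True, True, True),
        (200.0, 6.5, True, False, False),   # strict ">": boundary does not fire
        (200.0, 6.5, False, True, True),    # loose ">=": boundary fires
        (199.9, 6.4, False, False, False),
        (150.0, 6.0, True, False, False),
    ],
)
def test_lab_threshold_boundaries(catalog, glucose, hba1c, strict, glu_fires, a1c_fires):
    patient = make_patient(t1_codes=1, glucose=glucose, hba1c=hba1c)
    cfg = AlgorithmConfig(threshold_strict=strict)
    flags = t1dm_criteria(patient, cfg, catalog)
    assert flags.t1_glucose is glu_fires and flags.t1_hba1c is a1c_fires


def test_t1_criteria_require_a_t1_code(catalog):
    patient = make_patient(t1_codes=0, insulin_offset_days=0, glucose=300, hba1c=10)
    flags = t1dm_criteria(patient, AlgorithmConfig(), catalog)
    assert not (flags.t1_insulin90 or flags.t1_glucose or flags.t1_hba1c)


def test_t2_qualification_per_version(catalog):
    patient = make_patient(t2_codes=2)
    flags = t2dm_criteria(patient, AlgorithmConfig(version=V3), catalog)
    assert flags.t2_dx and not flags.t2_metformin
    # v1: code alone suffices; v3: metformin also required
    assert assign_phenotype(patient, AlgorithmConfig(version=V1), catalog).category is Category.T2DM
    assert assign_phenotype(patient, AlgorithmConfig(version=V3), catalog).category is Category.NO_DX
    with_met = make_patient(t2_codes=2, metformin=True)
    assert assign_phenotype(with_met, AlgorithmConfig(version=V3), catalog).category is Category.T2DM


def test_metformin_without_t2_code_is_not_t2(catalog):
    patient = make_patient(metformin=True)
    assert assign_phenotype(patient, AlgorithmConfig(version=V1), catalog).category is Category.NO_DX


def test_well_child_codes_are_no_dx(catalog):
    patient = make_patient(extra_dx=("Z00.129",))
    assert assign_phenotype(patient, AlgorithmConfig(), catalog).category is Category.NO_DX


def test_other_dm_precedes_t1_even_with_insulin(catalog):
    patient = make_patient(t1_codes=2, insulin_offset_days=10, other_code="P70.2")
    a = assign_phenotype(patient, AlgorithmConfig(version=V2), catalog)
    assert a.category is Category.OTHER_DM
    # under v1 the neonatal code P70.2 is unrecognized, so T1 rules decide
    a1 = assign_phenotype(patient, AlgorithmConfig(version=V1), catalog)
    assert a1.category is Category.T1DM


def test_tied_coding_with_both_criteria_is_indeterminate(catalog):
    patient = make_patient(t1_codes=2, t2_codes=2, insulin_offset_days=5, metformin=True)
    a = assign_phenotype(patient, AlgorithmConfig(version=V1), catalog)
    assert a.category is Category.INDETERMINATE
    # tie with only one side qualified is not indeterminate
    one_sided = make_patient(t1_codes=2, t2_codes=2, insulin_offset_days=5, metformin=False)
    assert assign_phenotype(one_sided, AlgorithmConfig(version=V3), catalog).category is Category.NO_DX


def test_over_18_flagged_ineligible(catalog):
    patient = make_patient(t1_codes=3, insulin_offset_days=0, birth=dt.date(1995, 5, 1))
    a = assign_phenotype(patient, AlgorithmConfig(), catalog)
    assert a.category is Category.NO_DX and a.age_ineligible


def test_adding_t1_codes_never_moves_toward_t2(catalog):
    """Monotonicity: extra T1DM-coded events only move the label toward T1DM."""
    rank = {Category.T2DM: 0, Category.NO_DX: 1, Category.INDETERMINATE: 2, Category.T1DM: 3}
    cfg = AlgorithmConfig(version=V1)
    for t2 in (0, 1, 2, 3):
        prev = None
        for t1 in range(0, 6):
            patient = make_patient(t1_codes=t1, t2_codes=t2, insulin_offset_days=0, metformin=True)
            cat = assign_phenotype(patient, cfg, catalog).category
            if prev is not None:
                assert rank[cat] >= rank[prev]
            prev = cat


def test_run_cohort_order_invariant_and_conserving(catalog):
    patients = [
        make_patient(patient_id=f"p{i}", t1_codes=i % 3, t2_codes=(i + 1) % 2,
                     insulin_offset_days=0 if i % 2 else None, metformin=i % 4 == 0)
        for i in range(12)
    ]
    cfg = AlgorithmConfig(version=V3)
    fwd, summary = run_cohort(patients, cfg, catalog)
    rev, _ = run_cohort(patients[::-1], cfg, catalog)
    assert {a.patient_id: a.category for a in fwd} == {a.patient_id: a.category for a in rev}
    assert sum(summary.counts.values()) == len(patients)
    assert summary.breakdown.groupby("dimension")["n"].sum().eq(len(patients)).all()


def test_run_cohort_rejects_empty_cohort(catalog):
    with pytest.raises(ValueError):
        run_cohort([], AlgorithmConfig(), catalog)
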