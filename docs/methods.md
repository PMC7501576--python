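# Methods

## The classification procedure

`pediphen` implements a deterministic, rule-based computable phenotype for
pediatric diabetes. For each patient the engine proceeds in a fixed order:

1. **Age eligibility.** Completed years on the index date (default
   2016-12-31, configurable) must be ≤ 18. Ineligible patients are retained
   in the output with `age_ineligible=True` rather than silently dropped,
   so extract errors stay auditable.
2. **Other-DM carve-out.** Any diagnosis code in the version-appropriate
   other-diabetes set (secondary diabetes E08/E09, other-specified E13
   covering MODY, neonatal diabetes) assigns OTHER_DM before the T1/T2
   decision. This ordering reflects that such patients are removed from the
   T1/T2 pools entirely, even when they also carry insulin orders or
   elevated labs; it is an interpretive choice, and the carve-out codes are
   user-overridable through the catalog file.
3. **Diagnosis ratio.** T1DM- and T2DM-classified code occurrences are
   counted. Strictly more of one type establishes the candidate type; equal
   nonzero counts are a tie. A tie with both types' criteria satisfied is
   INDETERMINATE — reported, and excluded from validation denominators. By
   default occurrences are code instances; `ratio_counting="encounters"`
   instead counts distinct diagnosis dates.
4. **Type-specific qualification.** T1DM requires at least one of: an
   insulin order within ±90 days of a T1DM-coded event, glucose > 200
   mg/dL, or HbA1c > 6.5 %. T2DM requires a T2DM code (v1/v2) plus a
   metformin prescription (v3). Candidates failing qualification fall back
   to NO_DX.

Every assignment carries the fired criteria flags and the ratio counts, so
any decision can be reconstructed from the output row.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `index_date` | 2016-12-31 | date | age-eligibility anchor of the development cohort; different deployments use calendar-year anchors |
| `insulin_window_days` | 90 | days | medication–diagnosis linkage window; applied **symmetrically** (±90) because an order may precede or follow the coded encounter. Direction/width configurable |
| `glucose_threshold_mgdl` | 200 | mg/dL | random-glucose criterion |
| `hba1c_threshold_pct` | 6.5 | % | glycated-hemoglobin criterion |
| `threshold_strict` | True | — | strict ">" comparisons by default; a switch to "≥" is provided because both conventions circulate for these cut-points |

The symmetric window is the least-assuming reading of "within 90 days";
an order-after-diagnosis-only variant can be emulated by pre-filtering the
medication table.

## The default code catalog

Diagnosis groupings ship as YAML (`src/pediphen/data/default_catalog.yaml`)
and are overridable per run. ICD-10: E10.\* → T1DM, E11.\* → T2DM,
E08.\*/E09.\*/E13.\* plus the neonatal code → other DM. ICD-9: the fifth
digit of 250.xx carries type (1/3 → T1DM, 0/2 → T2DM, enumerated exactly);
249.\* and 775.1 are placed in the other-DM set. The neonatal code is the
one rule that differs across algorithm revisions: v1 carried P61.0, v2
corrected it to P70.2 (neonatal diabetes mellitus). Code matching is
dot- and case-insensitive; prefix patterns (trailing `*`) match any
subclassification characters. The three active diagnosis sets are checked
pairwise disjoint at catalog construction, which makes per-code
classification a total function.

Medication classes are keyword sets over normalized drug names (insulin
analog names, metformin/Glucophage), not RxNorm concepts: extracts name
drugs inconsistently, and keyword matching is transparent and overridable.

## Validation arithmetic

Scoring is one-vs-rest per target category: for the T2DM target, gold-T1DM
and gold-no-diagnosis patients are both negatives. INDETERMINATE patients
are excluded from all four denominators. Percentages round half away from
zero to one decimal, matching how such review tables are reported. Zero
denominators yield an explicit undefined (`None`), never silent NaN. A
plain percent-agreement helper supports double-review reliability checks.

The bundled 295-record review fixture is built by exact integer allocation,
not sampling: the joint (assigned × reviewed) table is pinned by the two
confusion matrices — T1DM (124, 7, 4, 160) with the 7 false positives split
5 no-diagnosis / 2 T2DM, and T2DM (33, 31, 2, 229) — together with the
assigned marginals 131/64/100 and review marginals 128/35/132. These
constraints leave one degree of freedom: how the 4 T1DM false negatives
split between assigned-T2DM and assigned-no-diagnosis. The fixture carries
all 4 as assigned-no-diagnosis, which also satisfies the 100
assigned-no-diagnosis marginal; any other split would preserve both
confusion matrices but not that marginal.

## The synthetic cohort generator

The generator emulates what makes this classification hard in real
extracts, with every random draw taken from a single seeded generator so a
fixed spec is byte-reproducible:

- **Conflicting coding.** With probability `conflict_rate` (default 0.2) a
  diabetic patient accrues 1 to n−1 opposite-type codes under a strict
  majority of the true type; with probability `tie_rate` (default 0.025,
  about the tied fraction observed among diabetic records in development)
  the counts tie exactly. Tied patients are generated with mixed treatment
  (insulin anchored to a T1-coded encounter, plus metformin exposure), the
  clinical picture that makes a tie genuinely undecidable.
- **Labs.** One glucose and one HbA1c value per patient, drawn from
  truncated normal distributions whose means, SDs and truncation bounds
  default to the development cohort's per-group summaries (e.g. glucose
  89.43 (30.33) mg/dL for no-diagnosis, 207.59 (98.57) for T1DM, 161.11
  (96.83) for T2DM; HbA1c 5.48 (0.58), 9.27 (1.80), 7.92 (2.90) %). The
  truncated-normal family is a modeling choice; only mean/SD/range are
  constrained by data. Each lab is independently missing with
  `missing_lab_rate` (default 0.1).
- **Medications.** Insulin coverage for T1DM patients defaults to 0.92 (the
  insulin share observed among algorithm-identified T1DM patients at
  deployment scale), placed within the ±90-day window of a T1DM-coded
  encounter. Metformin coverage for T2DM defaults to 0.9, reflecting
  first-line metformin therapy in pediatric T2DM. Half of T2DM patients
  also receive insulin at an arbitrary encounter.
- **Demographics.** Ages are truncated-normal per group (T2DM oldest,
  other-DM youngest since neonatal forms dominate), birth dates back-solved
  from the index date so completed-years age lands in 0–18; sex, race and
  ethnicity follow per-group categorical probabilities. Events occur within
  the index year, never before birth.
- **Other DM.** One carve-out code per patient: with probability
  `neonatal_frac` (0.25) the neonatal code P70.2 — which the v1 rules do
  not recognize, reproducing that revision's known blind spot — otherwise
  an other-specified/secondary code present in every revision's set.

Because at most one glucose and one HbA1c are emitted per patient and
medication placement is always in-window, the probability a T1DM patient is
recovered has the closed form 1 − (1 − p_ins)(1 − p_glu)(1 − p_a1c), with
p_glu and p_a1c the product of lab availability and the truncated-normal
exceedance probability. The test suite and the acceptance script check
simulated sensitivity against this formula within 3 binomial standard
deviations at n = 1,000.

What passing these tests does **not** show: robustness to longitudinal care
patterns (multiple labs over years, medication discontinuation), unit
errors, coding-system migration mid-history, or site-specific code usage —
real extracts contain all of these, and the generator deliberately does
not.

## Numerical and degenerate-input choices

- Dates are strict ISO-8601; ambiguous formats are rejected, not guessed.
- Lab values outside plausibility bounds (glucose 1–2000 mg/dL, HbA1c
  2–20 %) are dropped with a warning; missing units are assumed mg/dL / %
  with a warning.
- Orphan events (no matching patient row) are counted, logged and dropped.
- Event streams are canonically sorted by (date, content), so classification
  is invariant to input row order; per-patient assignment is independent of
  cohort order.
- Percent rounding is half-away-from-zero (`floor(x + 0.5)` on the scaled
  value), so boundary cases like 6.25 % render 6.3.

## Known limitations

- The engine sees only the four tables; care-setting and encounter
  structure beyond the diagnosis date are not used in the default
  event-count ratio.
- v1/v2 T2DM assignment is by codes alone, so its PPV is intrinsically
  limited in populations with frequent rule-out coding; v3's metformin
  requirement trades sensitivity for PPV and can only shrink the T2DM set.
- The default catalog is a documented, standard-chapter grouping, not a
  site-verified list; deployments should review it against local coding
  practice and override via `--catalog`.
- Problem sizes in the test suite and acceptance script (cohorts of 300 and
  1,000) are the package's chosen verification scale; the rules themselves
  are O(events) per patient and run unchanged on much larger extracts.
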