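# pediphen

A computable phenotype for pediatric diabetes in electronic health record
(EHR) extracts. `pediphen` classifies every patient aged 18 or younger in a
flat-file EHR extract as **type 1 diabetes (T1DM)**, **type 2 diabetes
(T2DM)**, **other diabetes** (cystic fibrosis–related diabetes, MODY,
neonatal diabetes, secondary forms), or **no diagnosis**, using only
diagnosis codes, laboratory results and medication orders — no manual chart
review. It is aimed at clinical-informatics and epidemiology groups who need
to assemble pediatric diabetes cohorts from research data warehouses and
validate the selection against chart-review gold standards.

## The algorithm

A patient qualifies as **T1DM** if they are ≤ 18 years old on the index
date, carry an ICD-9/ICD-10 T1DM code (ICD-10 E10.\*, ICD-9 250.x1/250.x3)
and satisfy at least one of three disjunctive criteria:

1. an **insulin** order within 90 days of a T1DM-coded encounter,
2. a **glucose** result > 200 mg/dL, or
3. an **HbA1c** result > 6.5 %.

**T2DM** (E11.\*, 250.x0/250.x2) is assigned on diagnosis codes alone.
Conflicting T1DM/T2DM coding across encounters is resolved by the
**diagnosis ratio**: the type with strictly more code occurrences wins;
exactly tied counts with both types' criteria satisfied are *indeterminate*
and excluded from validation denominators.

Three published revisions of the rules are selectable:

| version | change |
|---|---|
| `v1` | original rules; neonatal diabetes coded as P61.0 in the other-DM set |
| `v2` | other-DM set recognizes neonatal diabetes mellitus as P70.2 instead of P61.0 |
| `v3` | T2DM additionally requires a metformin prescription |

Validation is one-vs-rest per target: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), reported as
percentages to one decimal.

The package also ships a seeded synthetic-EHR generator (known true category
per patient, configurable coding-conflict and tie rates, group-specific
truncated-normal lab distributions, prescribing and lab-missingness
probabilities) so every rule is exercisable without any real patient data.

## Worked example

Simulate a 300-patient cohort (100 T1DM / 100 T2DM / 100 healthy by
construction), classify it with the v1 rules, and score the output against
the generator's truth table:

```sh
pediphen simulate --out-dir demo --seed 5
pediphen run --patients demo/patients.csv --dx demo/diagnoses.csv \
    --labs demo/labs.csv --meds demo/meds.csv \
    --out demo/assignments.csv --version v1
```

which prints the category counts:

```
{"n": 300, "counts": {"T1DM": 95, "T2DM": 99, "OTHER_DM": 0, "NO_DX": 100, "INDETERMINATE": 6}}
```

Six patients received exactly tied T1DM/T2DM code counts with both types'
criteria met, so they are indeterminate; the remaining diabetic patients
are recovered. Scoring against truth (`truth.csv` recast as gold labels):

```sh
pediphen validate --assignments demo/assignments.csv --gold demo/gold.csv \
    --out demo/report.csv
cat demo/report.csv
```

```
category,n_reviewed,n_confirmed,sensitivity_pct,specificity_pct,ppv_pct,npv_pct,n_indeterminate_excluded
T1DM,95,95,100.0,100.0,100.0,100.0,6
T2DM,99,99,100.0,100.0,100.0,100.0,6
```

Every evaluable assignment matches truth here (the simulation used the
default high evidence coverage); `n_reviewed` is the number of
algorithm-positive patients per target and `n_confirmed` the true positives
among them. `pediphen fixture --out-dir DIR` emits the bundled 295-record
chart-review benchmark (assignments plus gold labels) whose confusion
matrices are (TP, FP, FN, TN) = (124, 7, 4, 160) for T1DM and
(33, 31, 2, 229) for T2DM.

The same functionality is available as a library:

```python
import pediphen as pp

catalog = pp.default_catalog()
records = pp.load_cohort("patients.csv", "diagnoses.csv", "labs.csv", "meds.csv",
                         catalog=catalog)
config = pp.AlgorithmConfig(version=pp.AlgorithmVersion.V3)
assignments, summary = pp.run_cohort(records, config, catalog)
```

## Layout

- `src/pediphen/codesets.py` — ICD code sets, medication keyword classes, the bundled default catalog (`data/default_catalog.yaml`, user-overridable)
- `src/pediphen/ehr_io.py` — EHR table schemas, loading with orphan/plausibility handling, assignment output
- `src/pediphen/engine.py` — the phenotype rules and cohort summaries
- `src/pediphen/validation.py` — confusion matrices and operating characteristics
- `src/pediphen/synthetic.py` — cohort generator and the chart-review fixture
- `src/pediphen/cli.py`, `config.py` — the `pediphen` command and run configuration

See `docs/methods.md` for the modeling choices and their rationale.
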