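# Default diagnosis code catalog for the pediatric diabetes phenotype.
#
# Pattern syntax: a trailing "*" marks a prefix pattern (matches the code and
# any subclassification characters, dot-insensitive); anything else is an
# exact code (also dot-insensitive).  ICD-9 diabetes type is carried by the
# fifth digit of 250.xx: 1/3 => type 1, 0/2 => type 2, so those are
# enumerated exactly rather than matched by prefix.
t1dm_dx:
  system: ICD
  patterns:
    - "E10*"
    - "250.01"
    - "250.03"
    - "250.11"
    - "250.13"
    - "250.21"
    - "250.23"
    - "250.31"
    - "250.33"
    - "250.41"
    - "250.43"
    - "250.51"
    - "250.53"
    - "250.61"
    - "250.63"
    - "250.71"
    - "250.73"
    - "250.81"
    - "250.83"
    - "250.91"
    - "250.93"
t2dm_dx:
  system: ICD
  patterns:
    - "E11*"
    - "250.00"
    - "250.02"
    - "250.10"
    - "250.12"
    - "250.20"
    - "250.22"
    - "250.30"
    - "250.32"
    - "250.40"
    - "250.42"
    - "250.50"
    - "250.52"
    - "250.60"
    - "250.62"
    - "250.70"
    - "250.72"
    - "250.80"
    - "250.82"
    - "250.90"
    - "250.92"
# Other diabetes forms (secondary / drug-induced / other specified, CFRD,
# MODY, neonatal).  v1 used P61.0 for neonatal diabetes; v2 corrected this
# to P70.2 (neonatal diabetes mellitus).
other_dm_dx_v1:
  system: ICD
  patterns:
    - "E08*"
    - "E09*"
    - "E13*"
    - "P61.0"
    - "249*"
    - "775.1"
other_dm_dx_v2:
  system: ICD
  patterns:
    - "E08*"
    - "E09*"
    - "E13*"
    - "P70.2"
    - "249*"
    - "775.1"
insulin_meds:
  system: MED_CLASS
  patterns:
    - "INSULIN"
    - "LISPRO"
    - "ASPART"
    - "GLARGINE"
    - "DETEMIR"
    - "DEGLUDEC"
    - "GLULISINE"
    - "NPH"
metformin_meds:
  system: MED_CLASS
  patterns:
    - "METFORMIN"
    - "GLUCOPHAGE"
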