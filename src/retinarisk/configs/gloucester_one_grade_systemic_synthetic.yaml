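# Illustrative SYNTHETIC coefficient set: one screening grade (the DR
# category at the index screening) plus HbA1c, total cholesterol and
# diabetes duration.  All numeric values are invented for demonstration and
# testing -- NOT the published coefficients.
model_id: gloucester_one_grade_systemic_synthetic
combine_mode: PH_POWER
grade_terms:
  NO_DR: 0.0
  MILD_ONE_EYE: 1.0
  MILD_BOTH_EYES: 1.5
terms:
  - variable: hba1c_pct
    beta: 0.4
    center: 6.8
  - variable: total_cholesterol
    beta: 0.2
    center: 5.0
  - variable: duration_years
    beta: 0.05
    center: 3.0
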