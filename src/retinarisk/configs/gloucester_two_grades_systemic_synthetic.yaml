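# Illustrative SYNTHETIC coefficient set: two screening grades plus systemic
# variables (HbA1c, total cholesterol) plus diabetes duration.  All numeric
# values are invented for demonstration and testing -- NOT the published
# coefficients.  The duration term may be omitted; the schema permits either.
model_id: gloucester_two_grades_systemic_synthetic
combine_mode: PH_POWER
group_terms:
  A: 0.0
  D: 1.9
  E: 1.4
  F: 1.2
  G: 1.6
  H: 1.1
  I: 2.0
terms:
  - variable: hba1c_pct
    beta: 0.35
    center: 6.8
  - variable: total_cholesterol
    beta: 0.18
    center: 5.0
  - variable: duration_years
    beta: 0.04
    center: 3.0
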