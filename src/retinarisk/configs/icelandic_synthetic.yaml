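# Illustrative SYNTHETIC coefficient set for the survival-model risk engine.
# Structure mirrors the published Icelandic-style model (retinopathy grade at
# the index screening, HbA1c, systolic BP; survival clock = years since
# diabetes diagnosis) but every numeric value here is invented for
# demonstration and testing -- these are NOT the published coefficients.
model_id: icelandic_synthetic
combine_mode: PH_POWER
baseline:
  family: weibull
  shape: 1.1
  scale: 75.0
terms:
  - variable: hba1c_pct
    beta: 0.45
    center: 6.8
  - variable: sbp
    beta: 0.02
    center: 136.0
grade_terms:
  NO_DR: 0.0
  MILD_ONE_EYE: 0.7
  MILD_BOTH_EYES: 1.1
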