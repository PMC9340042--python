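# Illustrative SYNTHETIC coefficient set: screening-grades-only variant.
# The score is the categorical coefficient of the two-screening risk group
# (A, D-I); groups B and C are never scored.  Values are invented, ordered
# loosely like observed progression rates (A lowest), and are NOT the
# published coefficients.
model_id: gloucester_two_grades_synthetic
combine_mode: PH_POWER
group_terms:
  A: 0.0
  D: 1.9
  E: 1.4
  F: 1.2
  G: 1.6
  H: 1.1
  I: 2.0
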