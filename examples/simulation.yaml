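# Demo synthetic-register configuration for `regburden simulate`.
n_persons: 500
seed: 7
study_start: 2000-01-01
study_end: 2015-12-31
lookback_start: 1995-01-01
incidence:
  mdd:
    base_rate: 0.03
  anxiety:
    base_rate: 0.02
  ihd:
    base_rate: 0.02
    age_multipliers:
      - {age_lo: 50, age_hi: 95, value: 3.0}
  migraine:
    base_rate: 0.015
  asthma:
    base_rate: 0.02
  low_back_pain:
    base_rate: 0.03
comorbidity_rr:
  mdd:
    circulatory: 2.0
    asthma: 1.5
mortality:
  - {age_lo: 0, age_hi: 60, value: 0.002}
  - {age_lo: 60, age_hi: 110, value: 0.03}
emigration_rate: 0.005
immigration_fraction: 0.1
repeat_diagnosis_rate: 0.4
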