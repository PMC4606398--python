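chm_arm:
  p_nonfatal_mi:
    base: 0.005
    low: 0.0
    high: 0.0119
  p_nonfatal_stroke:
    base: 0.0074
    low: 0.0
    high: 0.0158
  p_nonfatal_ua:
    base: 0.0149
    low: 0.0031
    high: 0.0267
  p_death:
    base: 0.005
    low: 0.0
    high: 0.0119
conv_arm:
  p_nonfatal_mi:
    base: 0.0175
    low: 0.0047
    high: 0.0303
  p_nonfatal_stroke:
    base: 0.015
    low: 0.0031
    high: 0.0269
  p_nonfatal_ua:
    base: 0.0399
    low: 0.0207
    high: 0.0591
  p_death:
    base: 0.0075
    low: 0.0
    high: 0.0159
long_term:
  event_free:
    p_mi:
      base: 0.018
      low: 0.01
      high: 0.02
    p_stroke:
      base: 0.007
      low: 0.001
      high: 0.009
    p_ua:
      base: 0.03
      low: 0.02
      high: 0.05
    p_death:
      base: 0.027
      low: 0.014
      high: 0.033
  post_mi:
    p_death_y1:
      base: 0.039
      low: 0.008
      high: 0.076
    p_death_later:
      base: 0.021
      low: 0.003
      high: 0.027
    p_mi_y1:
      base: 0.024
      low: 0.002
      high: 0.06
    p_mi_later:
      base: 0.018
      low: 0.001
      high: 0.008
    p_stroke_y1:
      base: 0.01
      low: 0.0024
      high: 0.024
    p_stroke_later:
      base: 0.007
      low: 0.0008
      high: 0.022
  post_ua:
    p_death_y1:
      base: 0.034
      low: 0.012
      high: 0.05
    p_death_later:
      base: 0.02
      low: 0.016
      high: 0.028
    p_mi_y1:
      base: 0.036
      low: 0.01
      high: 0.05
    p_mi_later:
      base: 0.011
      low: 0.01
      high: 0.063
    p_stroke_y1:
      base: 0.018
      low: 0.014
      high: 0.023
    p_stroke_later:
      base: 0.008
      low: 0.006
      high: 0.01
  post_stroke:
    p_death_y1:
      base: 0.115
      low: 0.066
      high: 0.189
    p_death_later:
      base: 0.035
      low: 0.016
      high: 0.061
    p_mi_y1:
      base: 0.003
      low: 0.002
      high: 0.006
    p_mi_later:
      base: 0.004
      low: 0.002
      high: 0.006
    p_stroke_y1:
      base: 0.128
      low: 0.064
      high: 0.189
    p_stroke_later:
      base: 0.04
      low: 0.03
      high: 0.08
  age_mace_or_per_10y:
    base: 0.5
    low: 0.33
    high: 0.87
utilities:
  u_event_free_chm:
    base: 0.818
    low: 0.418
    high: 0.848
  u_event_free_conv:
    base: 0.809
    low: 0.252
    high: 0.848
  d_mi:
    base: 0.127
    low: 0.108
    high: 0.147
  d_stroke:
    base: 0.139
    low: 0.118
    high: 0.16
  d_ua:
    base: 0.117
    low: 0.1
    high: 0.135
  d_death: 0.0
settings:
  horizon_years: 10
  cycle_length_years: 1.0
  discount_rate: 0.035
  half_cycle: trapezoid
  disutility_mode: persistent
  apply_age_or: false
  add_background_mortality: false
  cohort_size: 1000
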