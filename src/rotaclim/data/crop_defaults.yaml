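# Default crop, soil and management parameters for the rice-wheat rotation.
# Cardinal temperatures and thermal-time targets are generic for the two
# species (no station cultivar calibration is shipped); responses to CO2 are
# normalized at 350 ppm.  See docs/methods.md for units and rationale.
wheat:
  name: wheat
  tbase: 0.0
  topt: 26.0
  tupper: 34.0
  tt_emerge: 120.0
  tt_flower: 950.0
  tt_grainfill: 645.0
  photoperiod_sens: 0.08
  photoperiod_opt: 14.0
  vern_days: 30.0
  vern_tmin: -1.3
  vern_tmax: 15.7
  rue: 1.25
  k_ext: 0.55
  lai_max: 6.0
  cover_max: 0.93
  hi_rate: 0.011
  hi_cap: 0.48
  te_coeff: 0.006
  co2_rue_slope: 0.0007
  co2_te_slope: 0.0011
  rue_mod_cap: 1.5
  heat_threshold: 30.0
  heat_penalty: 0.004
  kc: 1.0
rice:
  name: rice
  tbase: 8.0
  topt: 30.0
  tupper: 42.0
  tt_emerge: 60.0
  tt_flower: 1050.0
  tt_grainfill: 520.0
  photoperiod_sens: 0.0
  vern_days: 0.0
  rue: 1.15
  k_ext: 0.6
  lai_max: 6.5
  cover_max: 0.95
  hi_rate: 0.013
  hi_cap: 0.50
  te_coeff: 0.008
  co2_rue_slope: 0.0007
  co2_te_slope: 0.0011
  rue_mod_cap: 1.5
  heat_threshold: 35.0
  heat_penalty: 0.004
  kc: 1.15
soil:
  capacity_mm: 150.0
  init_frac: 0.8
  drainage_coeff: 0.7
  soil_evap_coeff: 0.9
  runoff_threshold_mm: 50.0
  uptake_coeff: 0.12
management:
  wheat_sow: [10, 15]
  wheat_end: [6, 10]
  rice_sow: [6, 15]
  rice_end: [10, 14]
  rice_irrigated: true
  wheat_rainfed: true
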