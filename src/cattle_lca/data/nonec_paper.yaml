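name: nonec_paper
model_kind: non-EC
herd:
  herd_size: 10000000.0
  live_weight: 319.0
  fattening_days: 365.0
  enteric_ef: 65.0
  n_excretion_rate: 0.41
  manure_per_head_day: 22.0
planting:
  feed_intake_per_head_day: 9.0
  planting_area: 7066000.0
  fertilizer_application_rate: 679.33
  n_fertilizer_share: 0.3105
  compound_fertilizer_share: 0.5363
  compound_n_content: 0.2841
  straw_feed_fraction: 0.0988
  straw_burn_fraction: 0.8575
  is_silage: false
manure:
  return_rate: 0.45
  vs_rate: 10.8
  ms_fraction: 0.29
  mm_ch4_ef: 2.05
  mm_n2o_direct_ef: 0.01
  f_gas: 0.45
  f_leach: 0.02
factors:
  ef_farm_corn: 1.5
  ef_feed_corn: 0.0102
  ef_n_direct: 0.0105
  ef_n_vol_indirect: 0.01
  ef_n_leach_indirect: 0.0075
  f_gas_fert: 0.1
  f_gas_manure: 0.2
  f_leach_soil: 0.25
  burn_combustion_factor: 0.1
  ef_burn_co2: 1.39
  ef_burn_ch4: 0.00219
  ef_burn_n2o: 7.0e-05
  ef_mm_idn_vol: 0.01
  ef_mm_idn_leach: 0.011
gwp:
  gwp_ch4: 28.0
  gwp_n2o: 265.0
  gwp_n2o_manure_application: 273.0
overrides: {}
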