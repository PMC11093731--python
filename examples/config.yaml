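# Example pipeline configuration. Omitted keys keep package defaults.
scene:
  n_rows: 32
  n_cols: 32
  seed: 1
  noise_sd_reflectance: 0.01
  noise_sd_gpp: 1.0
  mean_annual_ta: 10.6
  depression:
    deciduous: 0.25
    mixed: 0.17
  years:
    - {year: 2020, type: normal}
    - {year: 2021, type: infestation}
    - {year: 2022, type: normal}
lue:
  epsilon0: 0.05
  tmin: 0.0
  topt: 20.0
  tmax: 40.0
run:
  n_dates_per_season: 20
  lut_step: 0.05
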