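label: breadfruit_ecocrop
criteria:
  temperature:
    units: degC
    abs_min: 16
    opt_min: 21
    opt_max: 33
    abs_max: 40
  rainfall:
    units: mm/yr
    abs_min: 1000
    opt_min: 1500
    opt_max: 3000
    abs_max: 3500
  solar_radiation:
    units: W/m^2
    abs_min: 20
    opt_min: 50
    opt_max: 197
    abs_max: 295
  soil_ph:
    units: pH
    abs_min: 4.3
    opt_min: 5.5
    opt_max: 6.5
    abs_max: 8.7
  drainage_class:
    units: class
    abs_min: 4
    opt_min: 4
    opt_max: 6
    abs_max: 6
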