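# Rootability rules for maize: piecewise-linear adequacy of soil factors.
#
# Each rule maps a layer variable to a rootability index RI (0-100%).
# `points` are [value, RI] breakpoints with strictly increasing values;
# outside the listed range the RI is constant at the nearest endpoint.
# The value at RI = 20 is the threshold value: a layer is inadequate for
# rooting when any evaluated factor falls strictly below the threshold index.
#
# Derived variables (computed per layer before evaluation):
#   vmc_sat    : VMC at saturation (v%), from the water retention curve
#   f_bd       : bd - (1.6 - 0.0035 * clay)   [kg/dm^3 above the critical BD]
#   d_sand     : sand[layer n] - sand[layer n-1]  (0 for the top layer)
#   d_clay     : clay[layer n] - clay[layer n-1]  (0 for the top layer)
#   f_exch_al  : exch_al * 100 / cec, clamped at 100  [% of CEC]
threshold_index: 20.0
rules:
  - factor: porosity_vmc_sat
    soil_factor: porosity
    variable: vmc_sat
    unit: "v%"
    points: [[0.0, 0.0], [27.5, 0.0], [30.0, 20.0], [40.0, 100.0], [100.0, 100.0]]
  - factor: porosity_f_bd
    soil_factor: porosity
    variable: f_bd
    unit: "kg/dm3"
    points: [[0.0, 100.0], [0.24, 20.0], [0.30, 0.0]]
  - factor: volume_cf
    soil_factor: volume
    variable: cf
    unit: "v%"
    points: [[0.0, 100.0], [80.0, 100.0], [88.0, 20.0], [90.0, 0.0], [100.0, 0.0]]
  - factor: texture_sand
    soil_factor: texture
    variable: sand
    unit: "g/100g"
    points: [[0.0, 100.0], [95.0, 100.0], [99.0, 20.0], [100.0, 0.0]]
  - factor: texture_d_sand
    soil_factor: texture
    variable: d_sand
    unit: "delta g/100g"
    points: [[0.0, 100.0], [30.0, 100.0], [50.0, 20.0], [55.0, 0.0], [100.0, 0.0]]
  - factor: texture_d_clay
    soil_factor: texture
    variable: d_clay
    unit: "delta g/100g"
    points: [[0.0, 100.0], [30.0, 100.0], [50.0, 20.0], [55.0, 0.0], [100.0, 0.0]]
  - factor: induration_caco3
    soil_factor: induration
    variable: caco3
    unit: "g/kg"
    points: [[0.0, 100.0], [150.0, 100.0], [400.0, 20.0], [450.0, 0.0], [1000.0, 0.0]]
  - factor: induration_caso4
    soil_factor: induration
    variable: caso4
    unit: "g/kg"
    points: [[0.0, 100.0], [50.0, 100.0], [300.0, 20.0], [350.0, 0.0], [1000.0, 0.0]]
  - factor: acidity_ph
    soil_factor: acidity
    variable: ph
    unit: "pH-H2O"
    points: [[1.0, 0.0], [3.63, 0.0], [4.0, 20.0], [5.5, 100.0], [12.0, 100.0]]
  - factor: alkalinity_ph
    soil_factor: alkalinity
    variable: ph
    unit: "pH-H2O"
    points: [[1.0, 100.0], [7.8, 100.0], [8.8, 20.0], [9.05, 0.0], [12.0, 0.0]]
  - factor: salinity_ec
    soil_factor: salinity
    variable: ec
    unit: "dS/m"
    points: [[0.0, 100.0], [1.5, 100.0], [5.7, 20.0], [6.75, 0.0]]
  - factor: sodicity_exch_na
    soil_factor: sodicity
    variable: exch_na
    unit: "cmolc/kg"
    points: [[0.0, 100.0], [1.0, 100.0], [4.2, 20.0], [5.0, 0.0]]
  - factor: toxicity_exch_al
    soil_factor: toxicity
    variable: exch_al
    unit: "cmolc/kg"
    points: [[0.0, 100.0], [2.5, 100.0], [5.7, 20.0], [6.5, 0.0]]
  - factor: toxicity_f_exch_al
    soil_factor: toxicity
    variable: f_exch_al
    unit: "% of CEC"
    points: [[0.0, 100.0], [35.0, 100.0], [75.0, 20.0], [85.0, 0.0], [100.0, 0.0]]
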