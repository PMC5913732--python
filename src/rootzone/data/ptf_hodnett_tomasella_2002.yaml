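# Van Genuchten parameter pedotransfer function for tropical soils.
#
# Source: Hodnett, M.G. & Tomasella, J. (2002). Marked differences between
# van Genuchten soil water-retention parameters for temperate and tropical
# soils: a new water-retention pedotransfer function developed for tropical
# soils. Geoderma 108, 155-180. Coefficients as commonly reproduced, e.g.
# Marthews et al. (2014), Geosci. Model Dev. 7, 711-723 (Table 2).
#
# Each parameter is a linear combination of the regressors below, with the
# whole sum multiplied by `scale` (the published table reports coefficients
# x 10^2). theta_s and theta_r come out in cm^3/cm^3; ln_alpha gives
# ln(alpha / kPa^-1) and is converted to cm^-1 by the loader
# (1 kPa = 10.19716 cm H2O); ln_n gives ln(n).
#
# Regressor unit conventions (normalisation from LayerProperties happens in
# ptf_params):
#   sand, silt, clay : g/100 g (mass %)
#   oc               : organic carbon, g/100 g (%)  [LayerProperties uses g/kg]
#   bd               : bulk density of fine earth, kg/dm^3
#   cec              : cmolc/kg
#   ph               : pH-H2O
#   clay_sq, silt_sq : squared terms; sand_clay, sand_silt: products
scale: 0.01
alpha_units: per_kPa
terms:
  theta_s:
    intercept: 81.799
    clay: 0.099
    bd: -31.42
    cec: 0.018
    ph: 0.451
    sand_clay: -0.0005
  theta_r:
    intercept: 22.733
    sand: -0.164
    cec: 0.235
    ph: -0.831
    clay_sq: 0.0018
    sand_clay: 0.0026
  ln_alpha:
    intercept: -2.294
    silt: -3.526
    oc: 2.440
    cec: -0.076
    ph: -11.331
    silt_sq: 0.019
  ln_n:
    intercept: 62.986
    clay: -0.833
    oc: -0.529
    ph: 0.593
    clay_sq: 0.007
    sand_silt: -0.014
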