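# rootzone

Rootable depth and root zone plant-available water holding capacity
(RZ-PAWHC) of soil, evaluated for maize from routinely measured soil
properties.

In rainfed cropping, the water a soil can offer a crop is bounded by three
things: how much plant-available water the fine earth holds per unit depth,
how much of the soil volume is fine earth rather than gravel and stones, and
how deep roots can actually go. `rootzone` implements a land-evaluation
framework that turns per-depth-interval soil properties (texture, organic
carbon, bulk density, CEC, pH-H₂O, coarse fragments, and optionally EC,
exchangeable Na/Al, CaCO₃, CaSO₄) plus profile-level drainage class and depth
to bedrock into:

- **PAWHC** (v%) per depth interval: θ(FC) − θ(PWP) of the soil fine earth,
  from van Genuchten retention curves θ(h) = θr + (θs − θr)/[1 + (αh)ⁿ]^m
  parameterised by a pedotransfer function for tropical soils
  (Hodnett & Tomasella, 2002). PWP is pF 4.2 (15,000 cm suction); FC is
  pF 2.0, 2.3 or 2.5 (100/200/300 cm), default 2.3.
- **SFEF**, the soil fine earth fraction: (100 − coarse fragments v%)/100.
- **RZD** (cm), the rootable depth: the shallowest of (a) the depth at which
  any soil factor's rootability index (RI) drops below the 20% threshold,
  (b) depth to bedrock, (c) depth of aerated soil from the drainage class
  (2.5x² + 22.5x − 15 for class x = 1..7), and (d) the maize genetic maximum
  of 150 cm. Fourteen piecewise-linear RI rules cover porosity (saturated
  VMC and texture-corrected bulk density), soil volume (coarse fragments),
  texture (sand content, abrupt sand/clay increases), induration (CaCO₃,
  CaSO₄), acidity and alkalinity (pH-H₂O), salinity (EC), sodicity
  (exchangeable Na) and aluminium toxicity (exchangeable Al and Al
  saturation of CEC).
- **RZ-PAWHC** (mm): PAWHC × SFEF integrated over [0, RZD]; 1 cm of soil at
  1 v% holds 0.1 mm, so an unrestricted 150 cm root zone at 10 v% holds
  150 mm.

It is aimed at agronomists and digital-soil-mapping practitioners who need
a transparent, rule-auditable soil-water evaluation — on profile tables or
on co-registered raster stacks — rather than a calibrated crop model.

## Worked example

```python
from rootzone import RunConfig, evaluate_profile, generate

profile = generate("sodic_lowland", n=1, seed=7)[0]
report = evaluate_profile(profile, config=RunConfig())

print("RZD: %.1f cm, limited by %s" % (report.depth.rzd, report.depth.limiting_factor))
print("sodicity RI per interval:",
      [round(float(x), 1) for x in report.factor_ri["sodicity_exch_na"]])
print("PAWHC per interval (v%):", [round(r.pawhc, 2) for r in report.retention])
print("RZ-PAWHC: %.1f mm" % report.water.rz_pawhc_mm)
```

prints

```
RZD: 40.9 cm, limited by sodicity_exch_na
sodicity RI per interval: [100.0, 100.0, 100.0, 2.0, 3.1, 3.1]
PAWHC per interval (v%): [11.33, 11.09, 10.93, 10.62, 10.36, 10.3]
RZ-PAWHC: 43.7 mm
```

The synthetic lowland profile is benign in the topsoil but its exchangeable
sodium rises well above the 4.2 cmolc/kg threshold below 30 cm, so the
sodicity RI collapses there (2–3%, far below the 20% threshold index). The
continuous RI(depth), interpolated through the interval midpoints, crosses
20% at 40.9 cm: that is the rootable depth, and only the water above it
(~10.3–11.3 v% of fine earth times the fine earth fraction) counts, giving
43.7 mm instead of the ~151 mm the full 150 cm column would hold.

The same pipeline runs from the shell:

```sh
rootzone generate --scenario mixed --n 200 --seed 7 --out fixtures.csv
rootzone evaluate --profiles fixtures.csv --fc-pf 2.3 --threshold-index 20 \
                  --max-depth 150 --out results.csv --summary summary.csv
```

`results.csv` has one row per profile (`profile_id, rzd_cm, limiting_factor,
rz_pawhc_mm`); `summary.csv` tabulates, per limiting factor, the extent
(km²), mean/sd of RZD (cm) and restricted soil volume (km³). Raster stacks
(ESRI ASCII grids, one file per property per depth interval) are evaluated
with `--raster-dir` and give results identical to the tabular path.

The rule set (`src/rootzone/data/rootability_rules.yaml`) and the PTF
coefficients are plain-text files and can be overridden with `--rules` /
`--ptf`, e.g. to rerun the sensitivity experiments (stricter threshold
index, different FC definition) as single-flag variations.

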