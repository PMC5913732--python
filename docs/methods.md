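# Methods

## Scope and decomposition

The package evaluates, per soil profile (or raster cell), the three
components whose product-over-depth is the root zone plant-available water
holding capacity:

1. plant-available water holding capacity of the soil fine earth per depth
   interval (PAWHC, v%),
2. the soil fine earth fraction per interval (SFEF, 0–1), and
3. the rootable depth (RZD, cm),

and aggregates them to RZ-PAWHC in mm. Inputs are expected on depth
intervals that are ordered, non-overlapping and contiguous from the surface;
the six GlobalSoilMap reporting intervals (0–5, 5–15, 15–30, 30–60, 60–100,
100–200 cm) are the documented default and what the synthetic generator
emits, but any contiguous layering is accepted. Depths are in cm, intervals
half-open [top, bottom). Evaluation truncates at the configured maximum crop
depth (150 cm for maize) even when inputs extend deeper.

Out of scope by design: geostatistical interpolation and covariate modelling
(inputs are taken as given, per profile or per cell), soil-morphology and
oxide-induration rootability factors (no operational parameterisation
exists), penetration resistance (management- and moisture-dependent),
capillary rise and soil-moisture dynamics, and uncertainty propagation.

## Water retention and PAWHC

Retention of the fine earth follows van Genuchten with the Mualem constraint
m = 1 − 1/n:

θ(h) = θr + (θs − θr) / [1 + (αh)ⁿ]^m,  h ≥ 0 in cm of suction.

Parameters are predicted by a pedotransfer function (PTF) developed for
tropical soils (Hodnett & Tomasella 2002, Geoderma 108:155–180), which takes
sand, silt and clay (g/100 g), organic carbon, bulk density of the fine
earth, CEC and pH-H₂O — the latter two as proxies for the low-activity-clay
mineralogy of highly weathered soils. The coefficients are not hard-coded:
they live in `data/ptf_hodnett_tomasella_2002.yaml` with their unit
conventions (OC in %, α fitted in kPa⁻¹ and converted to cm⁻¹ at
1 kPa = 10.19716 cm H₂O), and an alternative coefficient file of the same
form can be supplied per run. Unit normalisation from the package's layer
units (OC in g/kg) happens inside `ptf_params`.

Numerical guards: a regression PTF can emit slightly negative θr or n ≤ 1 on
extreme inputs; θr is clamped to 0 and n to 1.01, each with a warning, and
θs ≤ θr raises. θ(h) is evaluated in closed form; no fitting or optimisation
is involved.

PWP is fixed at pF 4.2 ≙ 15,000 cm. FC is configurable among pF 2.0, 2.3 and
2.5, mapped to 100, 200 and 300 cm — the stated conventional equivalences,
deliberately not 10^pF (10^2.3 ≈ 199.5). The default is pF 2.3, applied
uniformly; texture-dependent FC definitions are intentionally not
implemented because in a 3-D setting (texture varying across depth and
space) they produce inconsistent PAWHC fields. PAWHC = θ(FC) − θ(PWP) in v%;
monotonicity of θ(h) guarantees PAWHC ≥ 0 and PAWHC non-increasing in the FC
suction, both asserted property-wise in the tests.

SFEF = (100 − coarse fragments v%)/100.

## Rootability rules

Each of 14 rules maps one layer variable to a rootability index RI (0–100%),
piecewise-linear through published breakpoints pinned at RI levels
(100, 100, 20, 0, 0), constant beyond the outer breakpoints. The variable
value at RI = 20 is the threshold value; a layer is inadequate for rooting
when any evaluated factor falls strictly below the threshold index (RI = 20
exactly is adequate). The rule set ships as
`data/rootability_rules.yaml` and is overridable per run, which is how the
stricter-threshold sensitivity experiment (e.g. threshold 30%, moving the
acidity cutoff from pH 4.0 to ≈4.2) is reproduced.

Derived variables computed before rule evaluation:

- `f_bd = bd − (1.6 − 0.0035·clay)`: bulk density relative to a critical,
  texture-dependent bulk density (1.60 kg/dm³ for pure sand, 1.25 for pure
  clay). This single variable supersedes separate pore-volume/particle-
  density bookkeeping.
- `d_sand`, `d_clay`: the absolute increase of sand/clay content from one
  interval to the next, assigned to the deeper interval (surface interval
  0). The consecutive-interval difference is the operational definition used
  regardless of interval thickness; the nominal minimal distance of 15 cm
  over which such abrupt changes are considered valid is documented here but
  not enforced, as no thickness-dependent formula exists.
- `f_exch_al = exch_al·100/cec`, clamped at 100%; undefined (and skipped
  with a warning) when CEC ≤ 0.
- `vmc_sat`: θ(0) from the retention step, as the porosity proxy.

Missing optional inputs (EC, exchangeable Na/Al, CaCO₃, CaSO₄) cause the
corresponding factor to be skipped — excluded from the layer minimum and
logged — never treated as zero. Both pH rules (acidity low-bad, alkalinity
high-bad) are always evaluated; their breakpoints make simultaneous
restriction impossible.

### Restriction depth

Per factor, the interval RI values are interpolated linearly through the
interval midpoints (2.5, 10, 22.5, 45, 80, 150 cm on the standard
intervals), constant above the first and below the last midpoint, and the
restriction depth is the shallowest crossing below the threshold (0 cm when
the surface value is already below). Linear interpolation was chosen over a
smoothing spline: the rules themselves are piecewise-linear, the continuous
estimate stays within [0, 100] by construction, and a cubic spline could
overshoot. A brute-force 1 cm scan of the same interpolated profile serves
as an independent oracle in the tests (1,000 synthetic profiles, every
factor). Per-factor crossing followed by a minimum is equivalent, under
linear interpolation, to splining the factor minimum.

## Profile-level depths and the RZD decision

- Aeration: drainage class x ∈ {1..7} maps to aerated depth
  2.5x² + 22.5x − 15 cm (10, 40, 75, 115, 160, 210, 265). Classes ≥ 5 exceed
  the crop maximum and never limit.
- Bedrock: the minimum of the recorded depth to bedrock and the top of the
  shallowest layer with coarse fragments > 90 v% (such layers are treated as
  bedrock; exactly 90 v% is not).
- Crop maximum: 150 cm default.

RZD is the minimum of all present candidates; a missing drainage class or
bedrock record makes that candidate non-limiting (a censored observation is
a minimum soil depth, not evidence of restriction). Ties are attributed
deterministically by the fixed precedence crop maximum < bedrock < aeration
< layer factors (in rule-file order); the published framework needs a single
limiting factor per location but does not specify tie handling.

The limiting-factor summary reports, per factor, extent (km²), mean/sd of
RZD (cm) and restricted volume Σ area·(150 − RZD)·10⁻⁵ km³; the per-factor
volumes sum to the total restricted volume by construction (asserted).

## Aggregation

RZ-PAWHC (mm) = Σ over intervals of overlap([top,bottom], [0, RZD]) in cm ×
PAWHC(v%)/10 × SFEF. Intervals partially above RZD contribute pro rata
(continuous truncation — an aeration depth of 115 cm cuts the 100–200 cm
interval mid-way, it does not snap to a boundary), and nothing below the
crop maximum contributes. Both the absolute value and the RZD-weighted
means of PAWHC and SFEF are reported, plus a nested decomposition:
`unlimited` (a reference PAWHC of 10 v% over the full crop depth, i.e.
150 mm), `pawhc_limited` (actual PAWHC, full depth, SFEF = 1),
`pawhc_sfef_limited` (plus SFEF) and `full` (plus RZD truncation). The last
three are non-increasing in that order; `unlimited ≥ pawhc_limited` is not
guaranteed, since actual PAWHC may exceed the 10 v% reference.

## Synthetic data

The generator draws six-interval profiles whose marginals emulate a large
legacy soil-profile database for the region the framework targets: roughly
normal texture, pH, bulk density, CEC and drainage class; log-normal coarse
fragments, EC and exchangeable sodium (the strongly skewed properties);
organic carbon declining and clay mildly increasing with depth so the
texture-change rules are exercised. All draws stay inside that database's
published min–max envelopes (asserted in tests). A benign baseline evaluates
unrestricted; named scenarios (`sodic_lowland`, `shallow_bedrock`,
`poorly_drained`, `acid_toxic`, `gravelly`, `saline`, `unconstrained`,
`mixed`) inject adverse values below 30 cm. The `mixed` scenario cycles
deterministically through a 17-recipe catalogue engineered so that each of
the 14 rule factors, plus aeration, bedrock and the unrestricted case, is
the attributed limiting factor — injection magnitudes were chosen so exactly
one factor crosses the threshold shallowest (e.g. the dense-clean-sand
recipe drops saturated porosity below 27.5 v% while keeping f.BD's crossing
deeper). Seeding: one integer seed, split into independent per-profile
streams via `numpy.random.SeedSequence.spawn`, so profile k is reproducible
regardless of n.

What the generator does not emulate: spatial correlation between cells
(raster fixtures are i.i.d.), measurement error and inter-laboratory
heterogeneity, the co-occurrence structure of real pedons (e.g. sodicity
with alkalinity), and the smoothing of mapped predictions. Passing tests
therefore demonstrate correctness of the evaluation logic under realistic
marginal ranges, not predictive accuracy on real soil maps; headline
continental statistics (mean RZD, mean RZ-PAWHC, per-factor volumes)
require the real input rasters and are out of scope.

## Rasters

The raster path uses the ESRI ASCII grid format — a plain-text,
widely supported single-band raster — one file per property per depth
interval plus whole-profile grids. A stack must be strictly registered
(shape, cell size, origin, nodata value); no resampling or reprojection is
attempted. Nodata maps to "missing": optional properties become skipped
factors, missing required properties exclude the cell from evaluation and
are reported. Cell values round-trip via `repr`, so tabular and raster
evaluation of the same data agree exactly (tested to 1e-9 relative).

## Problem sizes and tolerances

The test suite runs the heavy property checks at 1,000 synthetic profiles
(restriction-depth brute force) and 1,002 layers (FC-ordering), with 4×4
raster grids — sizes at which the whole suite completes in seconds while
every code path and every rule factor is exercised. Breakpoint and analytic
identities are asserted exactly; floating-point comparisons use 1e-9
relative (path equivalence) or 1e-12 absolute (closed-form oracle); the
brute-force scan agrees with the analytic crossing within its 1 cm grid
step. Interval contiguity uses a 1e-6 cm tolerance; the texture sum is
validated to 100 ± 1 g/100 g.
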