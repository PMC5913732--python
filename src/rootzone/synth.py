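"""Seeded synthetic soil profile generator.

Profiles are drawn on the six GlobalSoilMap depth intervals with property
marginals shaped like continental legacy soil databases: roughly normal
texture, pH, bulk density and CEC; log-normal coarse fragments, electric
conductivity and exchangeable sodium (the highly skewed properties); organic
carbon declining and clay mildly increasing with depth, so the
texture-change rules are exercised.

A benign baseline profile evaluates unrestricted (RZD 150 cm). Scenario
presets inject adverse property values below 30 cm so that every rootability
factor, plus the aeration and bedrock limits, can be made the limiting
factor; the ``mixed`` scenario cycles deterministically through the full
recipe catalogue.

Seeding: one integer seed drives everything via ``numpy.random.SeedSequence``;
each profile gets its own child stream, so profile k is reproducible
independent of n.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .profiles import (
    STANDARD_INTERVALS,
    LayerProperties,
    ProfileMeta,
    SoilProfile,
)

#: layer indices of the standard intervals below 30 cm, where scenario
#: injections are applied
_DEEP = (3, 4, 5)


@dataclass(frozen=True)
class Scenario:
    name: str
    n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("scenario n must be >= 1")
        if self.name not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.name!r}; valid names: "
                f"{', '.join(sorted(SCENARIOS))}"
            )


def _base_profile(rng: np.random.Generator) -> tuple[list[dict], dict]:
    """Draw a benign baseline: evaluates to RZD = 150 cm, no restrictions."""
    n_layers = len(STANDARD_INTERVALS)
    clay0 = float(np.clip(rng.normal(26.0, 4.0), 18.0, 34.0))
    silt0 = float(np.clip(rng.normal(20.0, 4.0), 12.0, 28.0))
    oc0 = float(np.clip(rng.lognormal(np.log(15.0), 0.3), 5.0, 40.0))
    bd0 = float(np.clip(rng.normal(1.30, 0.05), 1.15, 1.42))
    cec0 = float(np.clip(rng.normal(15.0, 3.0), 8.0, 25.0))
    ph0 = float(np.clip(rng.normal(6.5, 0.25), 5.9, 7.4))

    layers = []
    for i in range(n_layers):
        clay = float(np.clip(clay0 + 1.2 * i + rng.normal(0, 0.5), 15.0, 42.0))
        silt = float(np.clip(silt0 + rng.normal(0, 0.5), 10.0, 30.0))
        sand = 100.0 - clay - silt
        layers.append(
            {
                "sand": sand,
                "silt": silt,
                "clay": clay,
                "oc": max(1.0, oc0 * 0.75**i),
                "bd": float(np.clip(bd0 + 0.01 * i, 1.15, 1.45)),
                "cec": cec0,
                "ph": ph0,
                "cf": float(np.clip(rng.lognormal(np.log(3.0), 0.8), 0.0, 25.0)),
                "ec": float(np.clip(rng.lognormal(np.log(0.1), 0.7), 0.0, 1.0)),
                "exch_na": float(
                    np.clip(rng.lognormal(np.log(0.1), 0.7), 0.0, 0.8)
                ),
                "exch_al": float(rng.uniform(0.0, 0.3)),
                "caco3": float(rng.uniform(0.0, 40.0)),
                "caso4": float(rng.uniform(0.0, 15.0)),
            }
        )
    meta = {
        "drainage_class": int(rng.choice([5, 6, 7])),
        "depth_to_bedrock": None,
    }
    return layers, meta


def _set_texture(layer: dict, sand: float, silt: float, clay: float) -> None:
    layer.update(sand=sand, silt=silt, clay=clay)


# --- injection recipes: each makes one specific factor the limiting one ----


def _porosity_vmc_sat(layers, meta, rng) -> None:
    # dense clean sand at depth: saturated porosity drops below 27.5 v%
    for i in _DEEP:
        _set_texture(layers[i], 95.0, 5.0, 0.0)
        layers[i].update(bd=1.86 + rng.uniform(0, 0.02), cec=4.0, ph=6.0, oc=2.0)


def _porosity_f_bd(layers, meta, rng) -> None:
    # compacted clayey subsoil: BD far above the critical texture-dependent BD
    for i in _DEEP:
        _set_texture(layers[i], 15.0, 25.0, 60.0)
        layers[i].update(bd=1.72 + rng.uniform(0, 0.02), cec=20.0, ph=6.2)


def _volume_cf(layers, meta, rng) -> None:
    # extremely gravelly subsoil, just below the 90 v% bedrock criterion
    for i in _DEEP:
        layers[i]["cf"] = 89.2 + rng.uniform(0, 0.4)


def _texture_sand(layers, meta, rng) -> None:
    # near pure, clean sand at depth; ramp at 30-60 cm keeps d_sand adequate
    _set_texture(layers[3], 75.0, 10.0, 15.0)
    for i in (4, 5):
        _set_texture(layers[i], 99.2 + rng.uniform(0, 0.2), 0.5, 0.3)
        layers[i]["silt"] = 100.0 - layers[i]["sand"] - 0.3


def _texture_d_sand(layers, meta, rng) -> None:
    # abrupt sand increase of ~52 g/100 g into the 60-100 cm interval
    _set_texture(layers[3], 40.0, 25.0, 35.0)
    for i in (4, 5):
        _set_texture(layers[i], 92.0 + rng.uniform(0, 0.5), 4.0, 4.0)
        layers[i]["silt"] = 100.0 - layers[i]["sand"] - 4.0


def _texture_d_clay(layers, meta, rng) -> None:
    # abrupt clay increase of ~52 g/100 g into the 60-100 cm interval
    _set_texture(layers[3], 60.0, 30.0, 10.0)
    for i in (4, 5):
        clay = 62.0 + rng.uniform(0, 0.5)
        _set_texture(layers[i], 18.0, 100.0 - 18.0 - clay, clay)


def _induration_caco3(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i]["caco3"] = 425.0 + rng.uniform(0, 10.0)


def _induration_caso4(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i]["caso4"] = 325.0 + rng.uniform(0, 10.0)


def _acidity(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i].update(ph=3.75 + rng.uniform(0, 0.1), exch_al=0.2)


def _alkalinity(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i]["ph"] = 8.92 + rng.uniform(0, 0.06)


def _salinity(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i]["ec"] = 6.2 + rng.uniform(0, 0.3)


def _sodicity(layers, meta, rng) -> None:
    # sodic lowland: exchangeable sodium rising well above 4.2 cmolc/kg
    # below 30 cm depth
    for i in _DEEP:
        layers[i]["exch_na"] = 4.7 + rng.uniform(0, 0.25)


def _toxicity_exch_al(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i].update(
            exch_al=6.05 + rng.uniform(0, 0.1), cec=30.0, ph=5.0
        )


def _toxicity_f_exch_al(layers, meta, rng) -> None:
    for i in _DEEP:
        layers[i].update(exch_al=4.05 + rng.uniform(0, 0.1), cec=5.0, ph=5.2)


def _aeration(layers, meta, rng) -> None:
    meta["drainage_class"] = int(rng.choice([1, 2, 3]))


def _bedrock(layers, meta, rng) -> None:
    meta["depth_to_bedrock"] = float(rng.uniform(35.0, 110.0))


def _none(layers, meta, rng) -> None:
    pass


def _acid_toxic(layers, meta, rng) -> None:
    _acidity(layers, meta, rng)
    for i in _DEEP:
        layers[i].update(exch_al=6.1 + rng.uniform(0, 0.2), cec=30.0)


#: recipe catalogue; the mixed scenario cycles through it in this order
RECIPES: dict[str, Callable] = {
    "porosity_vmc_sat": _porosity_vmc_sat,
    "porosity_f_bd": _porosity_f_bd,
    "volume_cf": _volume_cf,
    "texture_sand": _texture_sand,
    "texture_d_sand": _texture_d_sand,
    "texture_d_clay": _texture_d_clay,
    "induration_caco3": _induration_caco3,
    "induration_caso4": _induration_caso4,
    "acidity_ph": _acidity,
    "alkalinity_ph": _alkalinity,
    "salinity_ec": _salinity,
    "sodicity_exch_na": _sodicity,
    "toxicity_exch_al": _toxicity_exch_al,
    "toxicity_f_exch_al": _toxicity_f_exch_al,
    "depth_aeration": _aeration,
    "depth_soil": _bedrock,
    "unrestricted": _none,
}

SCENARIOS: dict[str, Sequence[str]] = {
    "unconstrained": ("unrestricted",),
    "sodic_lowland": ("sodicity_exch_na",),
    "shallow_bedrock": ("depth_soil",),
    "poorly_drained": ("depth_aeration",),
    "acid_toxic": ("acid_toxic",),
    "gravelly": ("volume_cf",),
    "saline": ("salinity_ec",),
    "mixed": tuple(RECIPES),
}

_RECIPE_FUNCS = dict(RECIPES, acid_toxic=_acid_toxic)


def generate(
    scenario: Scenario | str, n: int | None = None, seed: int | None = None
) -> list[SoilProfile]:
    """Generate ``n`` synthetic profiles for a scenario, reproducibly.

    ``scenario`` may be a :class:`Scenario` or a scenario name with ``n`` and
    ``seed`` given separately. Profile ids are ``{scenario}_{k:04d}``.
    """
    if isinstance(scenario, str):
        scenario = Scenario(name=scenario, n=n if n is not None else 10, seed=seed or 0)
    recipe_cycle = SCENARIOS[scenario.name]
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.n)

    profiles = []
    for k, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        layers, meta = _base_profile(rng)
        recipe = recipe_cycle[k % len(recipe_cycle)]
        _RECIPE_FUNCS[recipe](layers, meta, rng)
        profile = SoilProfile(
            meta=ProfileMeta(
                profile_id=f"{scenario.name}_{k:04d}",
                drainage_class=meta["drainage_class"],
                depth_to_bedrock=meta["depth_to_bedrock"],
            ),
            layers=[
                (interval, LayerProperties(**props))
                for interval, props in zip(STANDARD_INTERVALS, layers)
            ],
        )
        profiles.append(profile)
    return profiles


def generate_raster_fixture(
    scenario: Scenario | str,
    grid: tuple[int, int],
    seed: int | None = None,
    directory: str | Path = ".",
    nodata_cells: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[Path]:
    """Write a raster-stack fixture consistent with tabular generation.

    Generates ``rows x cols`` profiles (cell (r, c) is profile ``r*cols + c``)
    and writes one ASCII grid per property per depth interval plus the
    profile-level grids. ``nodata_cells`` punches nodata holes into the named
    property's grids (all intervals) at the given cells.

    Returns the list of files written.
    """
    from . import rasters  # local import to keep module load light

    rows, cols = grid
    if rows < 1 or cols < 1 or rows > 100 or cols > 100:
        raise ValidationError("grid must be between 1x1 and 100x100")
    if isinstance(scenario, str):
        scenario = Scenario(name=scenario, n=rows * cols, seed=seed or 0)
    elif scenario.n != rows * cols:
        raise ValidationError("scenario.n must equal rows*cols")
    profiles = generate(scenario)
    return rasters.write_raster_stack(
        profiles, grid, directory, nodata_cells=nodata_cells
    )
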