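"""Soil profile domain types and tabular I/O.

A :class:`SoilProfile` is a stack of depth intervals, each carrying the
measured (or mapped) properties of the soil fine earth in that interval, plus
whole-profile attributes (drainage class, depth to bedrock). Depths are in cm,
intervals are half-open ``[top, bottom)`` with the surface at 0; within one
profile intervals must be ordered, non-overlapping and contiguous from the
surface.

Tabular inputs are CSV/TSV with one row per profile x depth interval. Column
names can be remapped through a schema dictionary (canonical name -> actual
column name); see :data:`CANONICAL_COLUMNS`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: tolerance (cm) for interval contiguity checks
_DEPTH_TOL = 1e-6


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True, order=True)
class DepthInterval:
    """Half-open depth interval [top, bottom) in cm below the surface."""

    top: float
    bottom: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "top", float(self.top))
        object.__setattr__(self, "bottom", float(self.bottom))
        if self.top < 0:
            raise ValidationError(f"interval top must be >= 0, got {self.top}")
        if not self.bottom > self.top:
            raise ValidationError(
                f"interval bottom must exceed top: [{self.top}, {self.bottom})"
            )

    @property
    def thickness(self) -> float:
        return self.bottom - self.top

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top + self.bottom)

    def overlap(self, top: float, bottom: float) -> float:
        """Thickness (cm) of the overlap with [top, bottom)."""
        return max(0.0, min(self.bottom, bottom) - max(self.top, top))


#: the six GlobalSoilMap standard reporting intervals (cm)
STANDARD_INTERVALS: tuple[DepthInterval, ...] = (
    DepthInterval(0, 5),
    DepthInterval(5, 15),
    DepthInterval(15, 30),
    DepthInterval(30, 60),
    DepthInterval(60, 100),
    DepthInterval(100, 200),
)


@dataclass
class LayerProperties:
    """Soil fine earth properties of one depth interval.

    Required fields are the pedotransfer inputs plus coarse fragments:

    - ``sand``, ``silt``, ``clay``: mass fractions (g/100 g), summing to 100
    - ``oc``: organic carbon (g/kg)
    - ``bd``: bulk density of the fine earth (kg/dm^3)
    - ``cec``: cation exchange capacity (cmolc/kg)
    - ``ph``: pH-H2O
    - ``cf``: coarse fragments content (v%, 0-100)

    The chemistry fields used only by individual rootability factors
    (``ec`` dS/m, ``exch_na`` and ``exch_al`` cmolc/kg, ``caco3`` and
    ``caso4`` g/kg) are optional; ``None`` marks them as not measured, which
    makes the corresponding factor skip the layer rather than treat it as 0.
    """

    sand: float
    silt: float
    clay: float
    oc: float
    bd: float
    cec: float
    ph: float
    cf: float = 0.0
    ec: Optional[float] = None
    exch_na: Optional[float] = None
    exch_al: Optional[float] = None
    caco3: Optional[float] = None
    caso4: Optional[float] = None

    _OPTIONAL = ("ec", "exch_na", "exch_al", "caco3", "caso4")

    def __post_init__(self) -> None:
        for name in ("sand", "silt", "clay", "oc", "bd", "cec", "ph", "cf"):
            v = getattr(self, name)
            if _is_missing(v):
                raise ValidationError(f"required property {name!r} is missing")
            setattr(self, name, float(v))
        for name in self._OPTIONAL:
            v = getattr(self, name)
            if _is_missing(v):
                setattr(self, name, None)
            else:
                v = float(v)
                if v < 0:
                    raise ValidationError(f"{name} must be non-negative, got {v}")
                setattr(self, name, v)
        for name in ("sand", "silt", "clay", "cf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
        total = self.sand + self.silt + self.clay
        if abs(total - 100.0) > 1.0:
            raise ValidationError(
                f"sand+silt+clay must be within 100±1, got {total:.3f}"
            )
        if not 0.0 < self.bd <= 2.65:
            raise ValidationError(f"bulk density must be in (0, 2.65], got {self.bd}")
        if not 1.0 <= self.ph <= 14.0:
            raise ValidationError(f"pH must be in [1, 14], got {self.ph}")
        if self.oc < 0 or self.cec < 0:
            raise ValidationError("oc and cec must be non-negative")


@dataclass
class ProfileMeta:
    """Whole-profile attributes.

    ``drainage_class`` is the ordinal field assessment from very poorly
    drained (1) to excessively drained (7); ``depth_to_bedrock`` is in cm.
    Both are optional — when absent the corresponding depth limit is treated
    as non-limiting.
    """

    profile_id: str
    drainage_class: Optional[int] = None
    depth_to_bedrock: Optional[float] = None
    lon: Optional[float] = None
    lat: Optional[float] = None

    def __post_init__(self) -> None:
        self.profile_id = str(self.profile_id)
        if _is_missing(self.drainage_class):
            self.drainage_class = None
        else:
            dc = int(self.drainage_class)
            if dc not in range(1, 8):
                raise ValidationError(
                    f"profile {self.profile_id}: drainage class must be 1-7, got {dc}"
                )
            self.drainage_class = dc
        if _is_missing(self.depth_to_bedrock):
            self.depth_to_bedrock = None
        else:
            d = float(self.depth_to_bedrock)
            if d < 0:
                raise ValidationError(
                    f"profile {self.profile_id}: depth to bedrock must be >= 0"
                )
            self.depth_to_bedrock = d
        for name in ("lon", "lat"):
            if _is_missing(getattr(self, name)):
                setattr(self, name, None)


@dataclass
class SoilProfile:
    """One soil profile: metadata plus a contiguous stack of layers."""

    meta: ProfileMeta
    layers: list[tuple[DepthInterval, LayerProperties]]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError(
                f"profile {self.meta.profile_id}: at least one layer required"
            )
        self.layers = sorted(self.layers, key=lambda pair: pair[0].top)
        prev_bottom = 0.0
        for interval, _ in self.layers:
            if abs(interval.top - prev_bottom) > _DEPTH_TOL:
                raise ValidationError(
                    f"profile {self.meta.profile_id}: intervals are not "
                    f"contiguous from 0 (expected top {prev_bottom} cm, got "
                    f"{interval.top} cm)"
                )
            prev_bottom = interval.bottom

    @property
    def intervals(self) -> list[DepthInterval]:
        return [interval for interval, _ in self.layers]

    @property
    def properties(self) -> list[LayerProperties]:
        return [props for _, props in self.layers]

    @property
    def bottom(self) -> float:
        return self.layers[-1][0].bottom


#: canonical tabular column names (all lower case)
CANONICAL_COLUMNS = (
    "profile_id",
    "top",
    "bottom",
    "sand",
    "silt",
    "clay",
    "oc",
    "bd",
    "cec",
    "ph",
    "cf",
    "ec",
    "exch_na",
    "exch_al",
    "caco3",
    "caso4",
    "drainage_class",
    "depth_to_bedrock",
    "lon",
    "lat",
)

_REQUIRED_COLUMNS = (
    "profile_id",
    "top",
    "bottom",
    "sand",
    "silt",
    "clay",
    "oc",
    "bd",
    "cec",
    "ph",
    "cf",
)

_LAYER_OPTIONAL = ("ec", "exch_na", "exch_al", "caco3", "caso4")
_META_OPTIONAL = ("drainage_class", "depth_to_bedrock", "lon", "lat")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_profiles(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[SoilProfile]:
    """Read soil profiles from a CSV/TSV table, one row per layer.

    Parameters
    ----------
    path
        Tabular file with one row per profile x depth interval.
    schema
        Optional mapping from canonical column names (see
        :data:`CANONICAL_COLUMNS`) to the actual column names in the file.

    Returns
    -------
    list of :class:`SoilProfile`, sorted by profile id; layers re-sorted by
    top depth. Missing optional properties come back as ``None``, never 0.
    """
    path = Path(path)
    df = _read_table(path)
    schema = dict(schema or {})
    rename = {actual: canonical for canonical, actual in schema.items()}
    df = df.rename(columns=rename)

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    profiles: list[SoilProfile] = []
    for pid, group in df.groupby("profile_id", sort=True):
        first = group.iloc[0]
        meta = ProfileMeta(
            profile_id=str(pid),
            **{
                name: first[name] if name in group.columns else None
                for name in _META_OPTIONAL
            },
        )
        layers = []
        for _, row in group.iterrows():
            interval = DepthInterval(float(row["top"]), float(row["bottom"]))
            props = LayerProperties(
                sand=row["sand"],
                silt=row["silt"],
                clay=row["clay"],
                oc=row["oc"],
                bd=row["bd"],
                cec=row["cec"],
                ph=row["ph"],
                cf=row["cf"],
                **{
                    name: row[name] if name in group.columns else None
                    for name in _LAYER_OPTIONAL
                },
            )
            layers.append((interval, props))
        profiles.append(SoilProfile(meta=meta, layers=layers))
    if not profiles:
        raise ValidationError(f"{path}: no profiles found")
    return profiles


def profiles_to_frame(profiles: Iterable[SoilProfile]) -> pd.DataFrame:
    """Flatten profiles into the canonical one-row-per-layer table."""
    rows = []
    for profile in profiles:
        for interval, props in profile.layers:
            row = {
                "profile_id": profile.meta.profile_id,
                "top": interval.top,
                "bottom": interval.bottom,
            }
            for f in fields(LayerProperties):
                row[f.name] = getattr(props, f.name)
            row["drainage_class"] = profile.meta.drainage_class
            row["depth_to_bedrock"] = profile.meta.depth_to_bedrock
            row["lon"] = profile.meta.lon
            row["lat"] = profile.meta.lat
            rows.append(row)
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_profiles(profiles: Sequence[SoilProfile], path: str | Path) -> None:
    """Write profiles to CSV in the canonical column layout (lossless)."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles to write")
    profiles_to_frame(profiles).to_csv(Path(path), index=False)


def write_results(results: Sequence, path: str | Path) -> None:
    """Write one summary row per evaluated profile.

    Columns: ``profile_id, rzd_cm, limiting_factor, rz_pawhc_mm``. The
    limiting factor ``depth max`` (crop genetic maximum reached, i.e. soil
    unrestricted) is rendered as ``unrestricted``.

    ``results`` is a sequence of :class:`rootzone.aggregation.ProfileReport`.
    Raises :class:`ValidationError` on empty input, before touching the file.
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for report in results:
        factor = report.depth.limiting_factor
        rows.append(
            {
                "profile_id": report.profile_id,
                "rzd_cm": report.depth.rzd,
                "limiting_factor": "unrestricted" if factor == "depth max" else factor,
                "rz_pawhc_mm": report.water.rz_pawhc_mm,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_interval_details(results: Sequence, path: str | Path) -> None:
    """Write the per-interval detail table (one row per profile x interval)."""
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for report in results:
        for i, interval in enumerate(report.intervals):
            rows.append(
                {
                    "profile_id": report.profile_id,
                    "top": interval.top,
                    "bottom": interval.bottom,
                    "vmc_sat": report.retention[i].vmc_sat,
                    "vmc_fc": report.retention[i].vmc_fc,
                    "vmc_pwp": report.retention[i].vmc_pwp,
                    "pawhc": report.retention[i].pawhc,
                    "sfef": report.sfef[i],
                    "contribution_mm": report.water.per_interval_mm[i],
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), index=False)
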