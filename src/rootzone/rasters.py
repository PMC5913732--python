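"""Raster-stack input/output on the ESRI ASCII grid format.

Gridded evaluation mirrors the tabular path: one raster per soil property per
depth interval (files named ``{property}_{top}_{bottom}.asc``) plus
whole-profile grids ``drainage_class.asc`` and ``depth_to_bedrock.asc``. All
grids of one stack must be registered: same shape, cell size, origin and
nodata value. Nodata propagates to "missing", never to 0: an optional
property becomes ``None`` for that cell, a required property makes the whole
cell unusable and it is reported instead of evaluated.

The ASCII grid is a plain-text format: a six-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by one line of values
per grid row, top row first. Cell (row, col) of the array maps to profile
``row * ncols + col``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import AlignmentError, ValidationError
from .profiles import (
    DepthInterval,
    LayerProperties,
    ProfileMeta,
    SoilProfile,
)

_REQUIRED = ("sand", "silt", "clay", "oc", "bd", "cec", "ph", "cf")
_OPTIONAL = ("ec", "exch_na", "exch_al", "caco3", "caso4")
_PROFILE_LEVEL = ("drainage_class", "depth_to_bedrock")

_LAYER_FILE = re.compile(r"^(?P<prop>[a-z0-9_]+?)_(?P<top>\d+)_(?P<bottom>\d+)\.asc$")

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    nrows: int
    ncols: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    spec: GridSpec | None = None,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes nodata."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("ASCII grid data must be 2-D")
    if spec is None:
        spec = GridSpec(
            nrows=data.shape[0],
            ncols=data.shape[1],
            xllcorner=0.0,
            yllcorner=0.0,
            cellsize=1.0,
            nodata=DEFAULT_NODATA,
        )
    if data.shape != (spec.nrows, spec.ncols):
        raise ValidationError("data shape does not match grid spec")
    out = np.where(np.isnan(data), spec.nodata, data)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.xllcorner}\n"
        f"yllcorner {spec.yllcorner}\n"
        f"cellsize {spec.cellsize}\n"
        f"NODATA_value {spec.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    try:
        spec = GridSpec(
            nrows=int(header["nrows"]),
            ncols=int(header["ncols"]),
            xllcorner=header["xllcorner"],
            yllcorner=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header["nodata_value"],
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: malformed ASCII grid header") from exc
    if data.shape != (spec.nrows, spec.ncols):
        raise ValidationError(
            f"{path}: data shape {data.shape} does not match header "
            f"({spec.nrows}, {spec.ncols})"
        )
    data = np.where(data == spec.nodata, np.nan, data)
    return data, spec


def write_raster_stack(
    profiles: Sequence[SoilProfile],
    grid: tuple[int, int],
    directory: str | Path,
    nodata_cells: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[Path]:
    """Write per-property, per-interval grids from a list of profiles.

    All profiles must share the same depth intervals. ``nodata_cells`` maps a
    property name to cells (row, col) to blank out in every grid of that
    property.
    """
    rows, cols = grid
    profiles = list(profiles)
    if len(profiles) != rows * cols:
        raise ValidationError("number of profiles must equal rows*cols")
    intervals = profiles[0].intervals
    for p in profiles:
        if p.intervals != intervals:
            raise ValidationError(
                "all profiles must share the same depth intervals for rasterisation"
            )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodata_cells = {k: list(v) for k, v in (nodata_cells or {}).items()}

    def to_grid(values: list[Optional[float]], prop: str) -> np.ndarray:
        arr = np.array(
            [np.nan if v is None else float(v) for v in values], dtype=float
        ).reshape(rows, cols)
        for r, c in nodata_cells.get(prop, []):
            arr[r, c] = np.nan
        return arr

    written: list[Path] = []
    for li, interval in enumerate(intervals):
        for prop in _REQUIRED + _OPTIONAL:
            values = [getattr(p.properties[li], prop) for p in profiles]
            path = directory / f"{prop}_{int(interval.top)}_{int(interval.bottom)}.asc"
            write_ascii_grid(path, to_grid(values, prop))
            written.append(path)
    for prop in _PROFILE_LEVEL:
        values = [getattr(p.meta, prop) for p in profiles]
        path = directory / f"{prop}.asc"
        write_ascii_grid(path, to_grid(values, prop))
        written.append(path)
    return written


def read_raster_stack(
    directory: str | Path,
) -> tuple[list[SoilProfile], dict[str, list[str]]]:
    """Read a registered raster stack into per-cell soil profiles.

    Returns ``(profiles, missing)``: profiles for every cell whose required
    properties are complete, and a report mapping cell id (``r{row}_c{col}``)
    to the required properties that were nodata there. Optional properties
    that are nodata (or whose grids are absent) become ``None`` for that
    cell. Grids that do not share shape, cell size, origin and nodata raise
    :class:`AlignmentError`.
    """
    directory = Path(directory)
    layer_grids: dict[tuple[float, float], dict[str, np.ndarray]] = {}
    profile_grids: dict[str, np.ndarray] = {}
    spec: GridSpec | None = None

    files = sorted(directory.glob("*.asc"))
    if not files:
        raise ValidationError(f"{directory}: no .asc grids found")
    for path in files:
        data, this_spec = read_ascii_grid(path)
        if spec is None:
            spec = this_spec
        elif this_spec != spec:
            raise AlignmentError(
                f"{path.name}: grid does not match the stack "
                f"(expected {spec}, got {this_spec})"
            )
        m = _LAYER_FILE.match(path.name)
        if m and m.group("prop") not in _PROFILE_LEVEL:
            key = (float(m.group("top")), float(m.group("bottom")))
            layer_grids.setdefault(key, {})[m.group("prop")] = data
        elif path.stem in _PROFILE_LEVEL:
            profile_grids[path.stem] = data

    if not layer_grids:
        raise ValidationError(f"{directory}: no per-interval property grids found")
    intervals = [DepthInterval(t, b) for t, b in sorted(layer_grids)]
    for interval in intervals:
        grids = layer_grids[(interval.top, interval.bottom)]
        absent = [p for p in _REQUIRED if p not in grids]
        if absent:
            raise ValidationError(
                f"interval {interval.top:g}-{interval.bottom:g} cm lacks grids "
                f"for: {', '.join(absent)}"
            )

    profiles: list[SoilProfile] = []
    missing: dict[str, list[str]] = {}
    rows, cols = spec.nrows, spec.ncols
    for r in range(rows):
        for c in range(cols):
            cell = f"r{r}_c{c}"
            holes = []
            layers = []
            for interval in intervals:
                grids = layer_grids[(interval.top, interval.bottom)]
                props = {}
                for prop in _REQUIRED:
                    v = grids[prop][r, c]
                    if np.isnan(v):
                        holes.append(
                            f"{prop}@{interval.top:g}-{interval.bottom:g}cm"
                        )
                    else:
                        props[prop] = float(v)
                for prop in _OPTIONAL:
                    v = grids[prop][r, c] if prop in grids else np.nan
                    props[prop] = None if np.isnan(v) else float(v)
                if not holes:
                    layers.append((interval, LayerProperties(**props)))
            if holes:
                missing[cell] = holes
                continue
            dc = profile_grids.get("drainage_class")
            br = profile_grids.get("depth_to_bedrock")
            meta = ProfileMeta(
                profile_id=cell,
                drainage_class=(
                    None
                    if dc is None or np.isnan(dc[r, c])
                    else int(round(dc[r, c]))
                ),
                depth_to_bedrock=(
                    None if br is None or np.isnan(br[r, c]) else float(br[r, c])
                ),
            )
            profiles.append(SoilProfile(meta=meta, layers=layers))
    return profiles, missing
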