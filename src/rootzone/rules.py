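"""Rootability rules: per-layer adequacy of soil factors for root growth.

Each soil factor (porosity, volume, texture, induration, acidity, alkalinity,
salinity, sodicity, toxicity) is scored by a rootability index (RI, 0-100%),
a piecewise-linear function of one layer variable with published breakpoints.
A layer is adequate for rooting when every evaluated factor has RI at or
above the threshold index (default 20%); factors whose input is not measured
are skipped, not treated as zero.

The per-factor RI values of the six depth intervals are interpolated through
the interval midpoints to a continuous RI(depth), and the shallowest depth at
which RI(depth) drops below the threshold is that factor's restriction depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import EvaluationError, ValidationError
from .hydrology import RetentionSummary
from .profiles import DepthInterval, SoilProfile

logger = logging.getLogger(__name__)

#: threshold rootability index (%): restriction requires RI strictly below it
DEFAULT_THRESHOLD = 20.0

_RULES_RESOURCE = "rootability_rules.yaml"


@dataclass(frozen=True)
class ThresholdIndex:
    """Threshold RI separating adequate from fully restricted (default 20%)."""

    value: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 100.0:
            raise ValidationError(f"threshold index must be in (0, 100), got {self.value}")


@dataclass(frozen=True)
class RootabilityRule:
    """One piecewise-linear adequacy rule.

    ``points`` are (value, RI) breakpoints with strictly increasing values.
    Beyond the outer breakpoints the RI is constant. The rule is callable on
    scalars or arrays.
    """

    factor: str
    variable: str
    unit: str
    points: tuple[tuple[float, float], ...]
    soil_factor: str = ""

    def __post_init__(self) -> None:
        values = [v for v, _ in self.points]
        ris = [ri for _, ri in self.points]
        if len(self.points) < 2:
            raise ValidationError(f"rule {self.factor}: need >= 2 breakpoints")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValidationError(
                f"rule {self.factor}: breakpoint values must strictly increase"
            )
        if any(not 0.0 <= ri <= 100.0 for ri in ris):
            raise ValidationError(f"rule {self.factor}: RI levels must be in [0, 100]")

    def __call__(self, value):
        xs = np.array([v for v, _ in self.points])
        ys = np.array([ri for _, ri in self.points])
        out = np.interp(np.asarray(value, dtype=float), xs, ys)
        return float(out) if np.isscalar(value) else out

    def invert(self, ri: float) -> float:
        """Variable value at which the rule crosses ``ri`` on its scalable ramp.

        Scans the breakpoint segments in value order and linearly solves the
        first segment whose RI range brackets ``ri``; an exact breakpoint RI
        adjacent to a ramp returns the breakpoint value. Used to translate a
        stricter threshold index back into a property threshold (e.g. the
        acidity rule at RI 30% gives pH ~4.2 instead of 4.0).
        """
        pts = self.points
        for (v0, r0), (v1, r1) in zip(pts, pts[1:]):
            lo, hi = min(r0, r1), max(r0, r1)
            if r0 != r1 and lo <= ri <= hi:
                return v0 + (ri - r0) / (r1 - r0) * (v1 - v0)
        raise EvaluationError(
            f"rule {self.factor}: RI={ri} is not attained on any ramp"
        )

    @property
    def threshold_value(self) -> float:
        """The variable value pinned to RI = 20 (the threshold value)."""
        return self.invert(DEFAULT_THRESHOLD)


@lru_cache(maxsize=1)
def _default_rules() -> tuple[RootabilityRule, ...]:
    text = resources.files("rootzone.data").joinpath(_RULES_RESOURCE).read_text()
    return tuple(_parse_rules(text))


def load_rules(path: str | Path | None = None) -> list[RootabilityRule]:
    """Load the rootability rule set (default: the packaged rule file)."""
    if path is None:
        return list(_default_rules())
    return _parse_rules(Path(path).read_text())


def _parse_rules(text: str) -> list[RootabilityRule]:
    raw = yaml.safe_load(text)
    rules = [
        RootabilityRule(
            factor=entry["factor"],
            variable=entry["variable"],
            unit=entry.get("unit", ""),
            points=tuple((float(v), float(ri)) for v, ri in entry["points"]),
            soil_factor=entry.get("soil_factor", ""),
        )
        for entry in raw["rules"]
    ]
    return rules


def f_bd(bd: float, clay: float) -> float:
    """Bulk density relative to the critical, texture-dependent bulk density.

    f.BD = BD - (1.6 - 0.0035 x clay); the critical BD runs from 1.60 kg/dm^3
    for pure sand to 1.25 kg/dm^3 for pure clay. Positive values mean the
    layer is denser than critical.
    """
    if not 0.0 <= clay <= 100.0:
        raise ValidationError(f"clay must be in [0, 100], got {clay}")
    if bd <= 0:
        raise ValidationError(f"bulk density must be > 0, got {bd}")
    return bd - (1.6 - 0.0035 * clay)


def f_exch_al(exch_al: float, cec: float) -> float:
    """Exchangeable aluminium saturation (% of CEC), clamped at 100."""
    if exch_al < 0:
        raise ValidationError(f"exch_al must be >= 0, got {exch_al}")
    if cec <= 0:
        raise EvaluationError("aluminium saturation undefined for CEC <= 0")
    return min(100.0, exch_al * 100.0 / cec)


def texture_change(profile: SoilProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval absolute sand and clay increases between adjacent layers.

    The difference ``layer n - layer n-1`` is assigned to the deeper interval;
    the surface interval gets 0. A single-layer profile yields all zeros.
    """
    sand = np.array([p.sand for p in profile.properties])
    clay = np.array([p.clay for p in profile.properties])
    d_sand = np.zeros_like(sand)
    d_clay = np.zeros_like(clay)
    d_sand[1:] = np.diff(sand)
    d_clay[1:] = np.diff(clay)
    return d_sand, d_clay


def layer_variables(
    profile: SoilProfile, retention: Sequence[RetentionSummary]
) -> dict[str, np.ndarray]:
    """Assemble all rule variables per layer; NaN marks a skipped value."""
    props = profile.properties
    n = len(props)
    if len(retention) != n:
        raise ValidationError("retention must have one summary per layer")
    d_sand, d_clay = texture_change(profile)

    def optional(name: str) -> np.ndarray:
        return np.array(
            [np.nan if getattr(p, name) is None else getattr(p, name) for p in props]
        )

    al_sat = np.full(n, np.nan)
    for i, p in enumerate(props):
        if p.exch_al is not None:
            if p.cec > 0:
                al_sat[i] = f_exch_al(p.exch_al, p.cec)
            else:
                logger.warning(
                    "profile %s layer %d: CEC <= 0, aluminium saturation skipped",
                    profile.meta.profile_id,
                    i,
                )
    return {
        "vmc_sat": np.array([r.vmc_sat for r in retention]),
        "f_bd": np.array([f_bd(p.bd, p.clay) for p in props]),
        "cf": np.array([p.cf for p in props]),
        "sand": np.array([p.sand for p in props]),
        "d_sand": d_sand,
        "d_clay": d_clay,
        "caco3": optional("caco3"),
        "caso4": optional("caso4"),
        "ph": np.array([p.ph for p in props]),
        "ec": optional("ec"),
        "exch_na": optional("exch_na"),
        "exch_al": optional("exch_al"),
        "f_exch_al": al_sat,
    }


@dataclass
class LayerEvaluation:
    """Per-factor RI values and per-layer adequacy of one profile."""

    factor_ri: dict[str, np.ndarray]
    adequate: np.ndarray
    skipped: list[str] = field(default_factory=list)


def evaluate_layers(
    profile: SoilProfile,
    retention: Sequence[RetentionSummary],
    rules: Sequence[RootabilityRule] | None = None,
    threshold: float | ThresholdIndex = DEFAULT_THRESHOLD,
) -> LayerEvaluation:
    """Score every rule on every layer of a profile.

    A layer is adequate iff the minimum RI over the factors evaluated for it
    is at or above the threshold index (restriction requires RI strictly
    below the threshold). Factors whose variable is unmeasured in a layer are
    excluded from that layer's minimum; fully unmeasured factors are listed
    in ``skipped`` and logged.
    """
    rules = list(rules) if rules is not None else load_rules()
    thr = threshold.value if isinstance(threshold, ThresholdIndex) else float(threshold)
    variables = layer_variables(profile, retention)
    n = len(profile.layers)

    factor_ri: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for rule in rules:
        values = variables[rule.variable]
        ri = np.where(np.isnan(values), np.nan, rule(np.nan_to_num(values)))
        factor_ri[rule.factor] = ri
        if np.all(np.isnan(ri)):
            skipped.append(rule.factor)
            logger.info(
                "profile %s: factor %s skipped (no data)",
                profile.meta.profile_id,
                rule.factor,
            )

    stacked = np.vstack([factor_ri[r.factor] for r in rules])
    with np.errstate(invalid="ignore"):
        all_nan = np.all(np.isnan(stacked), axis=0)
        min_ri = np.where(all_nan, np.inf, np.nanmin(np.where(np.isnan(stacked), np.inf, stacked), axis=0))
    adequate = min_ri >= thr
    return LayerEvaluation(factor_ri=factor_ri, adequate=adequate, skipped=skipped)


def restriction_depth(
    ri: Sequence[float],
    intervals: Sequence[DepthInterval],
    threshold: float | ThresholdIndex = DEFAULT_THRESHOLD,
) -> Optional[float]:
    """Shallowest depth (cm) at which a factor's RI drops below the threshold.

    The per-interval RI values are linearly interpolated through the interval
    midpoints and held constant above the first and below the last midpoint.
    Returns ``None`` when the continuous RI never falls below the threshold.
    Intervals with NaN RI (unmeasured) are excluded from the interpolation.
    """
    thr = threshold.value if isinstance(threshold, ThresholdIndex) else float(threshold)
    ri = np.asarray(ri, dtype=float)
    mids = np.array([iv.midpoint for iv in intervals])
    mask = ~np.isnan(ri)
    if not mask.any():
        return None
    ri, mids = ri[mask], mids[mask]

    if ri[0] < thr:
        return 0.0
    for i in range(len(ri) - 1):
        if ri[i] >= thr > ri[i + 1]:
            return float(
                mids[i] + (ri[i] - thr) / (ri[i] - ri[i + 1]) * (mids[i + 1] - mids[i])
            )
    return None
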