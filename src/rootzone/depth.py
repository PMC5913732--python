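"""Profile-level depth limits and the rootable depth (RZD) decision.

RZD is the shallowest of four candidate depths: the crop's genetic maximum
(150 cm for maize), depth of soil to bedrock, depth of aerated soil derived
from the drainage class, and the shallowest layer-based restriction from the
rootability rules. The factor attaining the minimum is recorded as the
limiting factor; ties are broken by a fixed precedence (crop maximum, then
bedrock, then aeration, then the layer factors in rule order) so attribution
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profiles import SoilProfile

#: maximum potential root zone depth of maize (cm)
MAX_CROP_DEPTH = 150.0

#: coarse fragments content (v%) above which a layer counts as bedrock
BEDROCK_CF_THRESHOLD = 90.0

LIMIT_DEPTH_MAX = "depth max"
LIMIT_BEDROCK = "depth soil"
LIMIT_AERATION = "depth aeration"


@dataclass
class DepthEvaluation:
    """Candidate depths, the RZD decision and its limiting factor."""

    layer_restriction_depths: dict[str, Optional[float]]
    aeration_depth: Optional[float]
    bedrock_depth: Optional[float]
    max_crop_depth: float
    rzd: float
    limiting_factor: str


def aeration_depth(drainage_class: int) -> float:
    """Depth of aerated soil (cm) from the ordinal drainage class (1-7).

    The quadratic 2.5 x^2 + 22.5 x - 15 maps classes 1..7 to
    10, 40, 75, 115, 160, 210 and 265 cm.
    """
    x = int(drainage_class)
    if x not in range(1, 8):
        raise ValidationError(f"drainage class must be in 1..7, got {drainage_class}")
    return 2.5 * x * x + 22.5 * x - 15.0


def bedrock_depth(profile: SoilProfile) -> Optional[float]:
    """Depth of soil to bedrock (cm), or ``None`` when nothing indicates it.

    The recorded depth to bedrock is combined with the top depth of the
    shallowest layer whose coarse fragments content exceeds 90 v% (such
    layers are treated as bedrock); the minimum of the two applies.
    """
    candidates = []
    if profile.meta.depth_to_bedrock is not None:
        candidates.append(profile.meta.depth_to_bedrock)
    for interval, props in profile.layers:
        if props.cf > BEDROCK_CF_THRESHOLD:
            candidates.append(interval.top)
            break
    return min(candidates) if candidates else None


def rzd(
    profile: SoilProfile,
    layer_restrictions: Mapping[str, Optional[float]],
    max_crop_depth: float = MAX_CROP_DEPTH,
) -> DepthEvaluation:
    """Decide the rootable depth of one profile.

    ``layer_restrictions`` maps factor name to its restriction depth (cm) or
    ``None``. A missing drainage class or bedrock record makes that candidate
    non-limiting (logged by the caller); an aeration depth beyond the crop
    maximum never limits.
    """
    aeration = (
        aeration_depth(profile.meta.drainage_class)
        if profile.meta.drainage_class is not None
        else None
    )
    bedrock = bedrock_depth(profile)

    # precedence order for tie-breaking attribution
    candidates: list[tuple[str, float]] = [(LIMIT_DEPTH_MAX, max_crop_depth)]
    if bedrock is not None:
        candidates.append((LIMIT_BEDROCK, bedrock))
    if aeration is not None:
        candidates.append((LIMIT_AERATION, aeration))
    for factor, depth in layer_restrictions.items():
        if depth is not None:
            candidates.append((factor, depth))

    depth_min = min(d for _, d in candidates)
    limiting = next(name for name, d in candidates if d == depth_min)
    return DepthEvaluation(
        layer_restriction_depths=dict(layer_restrictions),
        aeration_depth=aeration,
        bedrock_depth=bedrock,
        max_crop_depth=max_crop_depth,
        rzd=depth_min,
        limiting_factor=limiting,
    )


def summarize_limiting_factors(
    evaluations: Sequence[DepthEvaluation],
    areas_km2: Sequence[float] | float = 1.0,
    max_crop_depth: float = MAX_CROP_DEPTH,
) -> pd.DataFrame:
    """Extent, degree and severity of each limiting factor.

    For every limiting factor: the extent (km^2) it limits, the mean and
    standard deviation of RZD over that extent (cm), and the restricted soil
    volume ``sum(area x (max_crop_depth - rzd) x 1e-5)`` in km^3 (1 cm =
    1e-5 km). The extents partition the total area and the factor volumes sum
    to the total restricted volume.
    """
    evaluations = list(evaluations)
    if not evaluations:
        raise ValidationError("no evaluations to summarise")
    if np.isscalar(areas_km2):
        areas = np.full(len(evaluations), float(areas_km2))
    else:
        areas = np.asarray(areas_km2, dtype=float)
        if len(areas) != len(evaluations):
            raise ValidationError("areas_km2 must match evaluations in length")

    rows = []
    factors = sorted({e.limiting_factor for e in evaluations})
    for factor in factors:
        idx = [i for i, e in enumerate(evaluations) if e.limiting_factor == factor]
        depths = np.array([evaluations[i].rzd for i in idx])
        a = areas[idx]
        volume = float(np.sum(a * (max_crop_depth - depths) * 1e-5))
        rows.append(
            {
                "factor": factor,
                "extent_km2": float(a.sum()),
                "mean_rzd_cm": float(depths.mean()),
                "sd_rzd_cm": float(depths.std(ddof=0)),
                "restricted_volume_km3": volume,
            }
        )
    return pd.DataFrame(rows)
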