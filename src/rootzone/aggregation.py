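"""Aggregation of layer water capacity over the rootable depth.

The root zone plant-available water holding capacity (RZ-PAWHC, mm) of a
profile is the per-interval PAWHC (v% of the fine earth) times the soil fine
earth fraction, summed over the interval thickness that overlaps [0, RZD]:
1 cm of soil holding 1 v% stores 0.1 mm of water, so a 150 cm root zone at a
default PAWHC of 10 v% with no coarse fragments holds 150 mm.

``evaluate_profile`` is the end-to-end pipeline for one profile: retention by
pedotransfer, rootability rules, restriction depths, the RZD decision and the
water aggregation, collected into a serialisable :class:`ProfileReport`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .depth import MAX_CROP_DEPTH, DepthEvaluation, rzd as decide_rzd
from .errors import ValidationError
from .hydrology import (
    RetentionSummary,
    SuctionConfig,
    layer_retention,
    load_ptf_coefficients,
    sfef,
)
from .profiles import DepthInterval, LayerProperties, ProfileMeta, SoilProfile
from .rules import (
    LayerEvaluation,
    RootabilityRule,
    evaluate_layers,
    load_rules,
    restriction_depth,
)


@dataclass
class RZPAWHCResult:
    """Water capacity of one profile aggregated over its root zone.

    ``decomposition_mm`` holds the nested what-if members: ``unlimited``
    (reference PAWHC over the full crop depth), ``pawhc_limited`` (actual
    PAWHC, full depth, no coarse fragments), ``pawhc_sfef_limited`` (plus the
    fine earth fraction) and ``full`` (plus truncation at RZD, which equals
    ``rz_pawhc_mm``).
    """

    rz_pawhc_mm: float
    per_interval_mm: list[float]
    pawhc_weighted_v: float
    sfef_weighted: float
    decomposition_mm: dict[str, float]


def rz_pawhc(
    profile: SoilProfile,
    retention: Sequence[RetentionSummary],
    depth_eval: DepthEvaluation,
    max_crop_depth: float = MAX_CROP_DEPTH,
    reference_pawhc_v: float = 10.0,
) -> RZPAWHCResult:
    """Aggregate PAWHC x SFEF over the rootable depth into mm of water.

    Intervals partially above RZD contribute pro rata by thickness; layers
    below the crop maximum contribute only their overlap with
    [0, max_crop_depth]. An RZD of 0 yields a valid 0 mm result.
    """
    if len(retention) != len(profile.layers):
        raise ValidationError("retention must have one summary per layer")
    root_limit = min(depth_eval.rzd, max_crop_depth)

    per_interval = []
    pawhc_full = sfef_full = 0.0
    pawhc_wsum = sfef_wsum = overlap_sum = 0.0
    for (interval, props), summary in zip(profile.layers, retention):
        fine = sfef(props.cf)
        # contribution within the root zone
        d_root = interval.overlap(0.0, root_limit)
        per_interval.append(d_root * summary.pawhc * 0.1 * fine)
        pawhc_wsum += d_root * summary.pawhc
        sfef_wsum += d_root * fine
        overlap_sum += d_root
        # decomposition members over the full crop depth
        d_crop = interval.overlap(0.0, max_crop_depth)
        pawhc_full += d_crop * summary.pawhc * 0.1
        sfef_full += d_crop * summary.pawhc * 0.1 * fine

    total = float(sum(per_interval))
    return RZPAWHCResult(
        rz_pawhc_mm=total,
        per_interval_mm=[float(x) for x in per_interval],
        pawhc_weighted_v=float(pawhc_wsum / overlap_sum) if overlap_sum > 0 else 0.0,
        sfef_weighted=float(sfef_wsum / overlap_sum) if overlap_sum > 0 else 0.0,
        decomposition_mm={
            "unlimited": max_crop_depth * reference_pawhc_v * 0.1,
            "pawhc_limited": float(pawhc_full),
            "pawhc_sfef_limited": float(sfef_full),
            "full": total,
        },
    )


@dataclass
class ProfileReport:
    """Every intermediate of one profile evaluation, JSON-serialisable."""

    profile_id: str
    intervals: list[DepthInterval]
    retention: list[RetentionSummary]
    sfef: list[float]
    factor_ri: dict[str, list[float]]
    skipped_factors: list[str]
    restriction_depths: dict[str, Optional[float]]
    depth: DepthEvaluation
    water: RZPAWHCResult

    def to_dict(self) -> dict:
        d = asdict(self)
        # NaN is not valid JSON; encode skipped layer RI as None
        d["factor_ri"] = {
            k: [None if np.isnan(v) else float(v) for v in vals]
            for k, vals in self.factor_ri.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileReport":
        return cls(
            profile_id=d["profile_id"],
            intervals=[DepthInterval(**iv) for iv in d["intervals"]],
            retention=[RetentionSummary(**r) for r in d["retention"]],
            sfef=list(d["sfef"]),
            factor_ri={
                k: [np.nan if v is None else float(v) for v in vals]
                for k, vals in d["factor_ri"].items()
            },
            skipped_factors=list(d["skipped_factors"]),
            restriction_depths=dict(d["restriction_depths"]),
            depth=DepthEvaluation(**d["depth"]),
            water=RZPAWHCResult(**d["water"]),
        )


def evaluate_profile(
    profile: SoilProfile,
    config: RunConfig | None = None,
    rules: Sequence[RootabilityRule] | None = None,
    retention: Sequence[RetentionSummary] | None = None,
    ptf_coefficients: dict | None = None,
) -> ProfileReport:
    """Run the full evaluation pipeline for one profile.

    ``retention`` injects precomputed retention summaries (bypassing the
    pedotransfer step), e.g. when measured water retention is available.
    """
    config = config or RunConfig()
    if rules is None:
        rules = load_rules(config.rules_file)
    if ptf_coefficients is None and config.ptf_coefficients:
        ptf_coefficients = load_ptf_coefficients(config.ptf_coefficients)
    suction = SuctionConfig(fc_pf=config.fc_pf)

    if retention is None:
        retention = [
            layer_retention(props, suction, coefficients=ptf_coefficients)
            for props in profile.properties
        ]
    retention = list(retention)

    evaluation = evaluate_layers(
        profile, retention, rules=rules, threshold=config.threshold_index
    )
    restrictions = {
        rule.factor: restriction_depth(
            evaluation.factor_ri[rule.factor],
            profile.intervals,
            config.threshold_index,
        )
        for rule in rules
    }
    depth_eval = decide_rzd(profile, restrictions, config.max_crop_depth)
    water = rz_pawhc(
        profile,
        retention,
        depth_eval,
        max_crop_depth=config.max_crop_depth,
        reference_pawhc_v=config.reference_pawhc_v,
    )
    return ProfileReport(
        profile_id=profile.meta.profile_id,
        intervals=profile.intervals,
        retention=retention,
        sfef=[sfef(p.cf) for p in profile.properties],
        factor_ri={k: list(v) for k, v in evaluation.factor_ri.items()},
        skipped_factors=evaluation.skipped,
        restriction_depths=restrictions,
        depth=depth_eval,
        water=water,
    )


def evaluate_profiles(
    profiles: Sequence[SoilProfile],
    config: RunConfig | None = None,
    **kwargs,
) -> list[ProfileReport]:
    """Evaluate a batch of profiles with one shared configuration."""
    config = config or RunConfig()
    rules = kwargs.pop("rules", None) or load_rules(config.rules_file)
    return [
        evaluate_profile(p, config=config, rules=rules, **kwargs) for p in profiles
    ]
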