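"""Water retention, pedotransfer parameterisation and fine earth fraction.

The water retention curve of the soil fine earth follows van Genuchten:

    theta(h) = theta_r + (theta_s - theta_r) / (1 + (alpha h)^n)^m,  m = 1 - 1/n

with suction head h in cm. Parameters are predicted from routinely measured
properties (texture, organic carbon, bulk density, CEC, pH-H2O) by a
pedotransfer function developed for tropical soils, whose coefficients ship
as a versioned plain-text file (see ``data/ptf_hodnett_tomasella_2002.yaml``)
and can be swapped for another coefficient set of the same form.

Plant-available water holding capacity (PAWHC, v%) of a layer is the
difference between the volumetric moisture content (VMC) at field capacity
and at permanent wilting point. PWP is fixed at pF 4.2 (15,000 cm suction);
FC may be defined at pF 2.0, 2.3 or 2.5, mapped to suctions of 100, 200 and
300 cm respectively (the conventional equivalences, not 10**pF).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .errors import EvaluationError, ValidationError
from .profiles import LayerProperties

logger = logging.getLogger(__name__)

#: 1 kPa of suction expressed in cm of water column
KPA_TO_CM = 10.19716

#: suction heads (cm) equivalent to the supported field capacity definitions
FC_SUCTION_CM: Mapping[float, float] = {2.0: 100.0, 2.3: 200.0, 2.5: 300.0}

#: permanent wilting point: pF 4.2, i.e. 15,000 cm of suction
PWP_PF = 4.2
PWP_SUCTION_CM = 15000.0


@dataclass(frozen=True)
class VanGenuchtenParams:
    """Van Genuchten retention parameters (Mualem constraint m = 1 - 1/n)."""

    theta_r: float
    theta_s: float
    alpha: float  # 1/cm
    n: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_r < self.theta_s <= 1.0:
            raise ValidationError(
                f"need 0 <= theta_r < theta_s <= 1, got theta_r={self.theta_r}, "
                f"theta_s={self.theta_s}"
            )
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if self.n <= 1:
            raise ValidationError(f"n must be > 1, got {self.n}")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


@dataclass(frozen=True)
class SuctionConfig:
    """Field capacity / wilting point definition used throughout a run."""

    fc_pf: float = 2.3

    def __post_init__(self) -> None:
        if self.fc_pf not in FC_SUCTION_CM:
            raise ValidationError(
                f"fc_pf must be one of {sorted(FC_SUCTION_CM)}, got {self.fc_pf}"
            )

    @property
    def fc_suction_cm(self) -> float:
        return FC_SUCTION_CM[self.fc_pf]

    @property
    def pwp_pf(self) -> float:
        return PWP_PF

    @property
    def pwp_suction_cm(self) -> float:
        return PWP_SUCTION_CM


@dataclass(frozen=True)
class RetentionSummary:
    """VMC (v%) at saturation, field capacity and wilting point of one layer."""

    vmc_sat: float
    vmc_fc: float
    vmc_pwp: float

    def __post_init__(self) -> None:
        if not self.vmc_sat >= self.vmc_fc >= self.vmc_pwp >= 0.0:
            raise ValidationError(
                "retention ordering violated: need vmc_sat >= vmc_fc >= "
                f"vmc_pwp >= 0, got {self.vmc_sat}, {self.vmc_fc}, {self.vmc_pwp}"
            )

    @property
    def pawhc(self) -> float:
        """Plant-available water holding capacity of the fine earth (v%)."""
        return self.vmc_fc - self.vmc_pwp


def vg_theta(h, params: VanGenuchtenParams):
    """Volumetric moisture content (cm^3/cm^3) at suction head ``h`` (cm).

    Accepts a scalar or array of non-negative suction heads.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValidationError("suction head h must be >= 0")
    se = (1.0 + (params.alpha * h_arr) ** params.n) ** (-params.m)
    theta = params.theta_r + (params.theta_s - params.theta_r) * se
    return float(theta) if np.isscalar(h) or h_arr.ndim == 0 else theta


_PTF_RESOURCE = "ptf_hodnett_tomasella_2002.yaml"
_PTF_INPUTS = ("sand", "silt", "clay", "oc", "bd", "cec", "ph")


@lru_cache(maxsize=None)
def _default_ptf_text() -> str:
    return resources.files("rootzone.data").joinpath(_PTF_RESOURCE).read_text()


@lru_cache(maxsize=1)
def _default_ptf_coefficients() -> dict:
    return _parse_coefficients(_default_ptf_text())


def _parse_coefficients(text: str) -> dict:
    coeffs = yaml.safe_load(text)
    for key in ("scale", "terms"):
        if key not in coeffs:
            raise ValidationError(f"PTF coefficients file lacks {key!r}")
    return coeffs


def load_ptf_coefficients(path: str | Path | None = None) -> dict:
    """Load a PTF coefficient set; defaults to the packaged tropical-soil set.

    The default set is cached; treat the returned mapping as read-only.
    """
    if path is None:
        return _default_ptf_coefficients()
    text = Path(path).read_text()
    return _parse_coefficients(text)


def _regressors(layer: LayerProperties) -> dict[str, float]:
    sand, silt, clay = layer.sand, layer.silt, layer.clay
    oc_pct = layer.oc / 10.0  # g/kg -> %
    return {
        "intercept": 1.0,
        "sand": sand,
        "silt": silt,
        "clay": clay,
        "oc": oc_pct,
        "bd": layer.bd,
        "cec": layer.cec,
        "ph": layer.ph,
        "clay_sq": clay * clay,
        "silt_sq": silt * silt,
        "sand_clay": sand * clay,
        "sand_silt": sand * silt,
    }


def ptf_params(
    layer: LayerProperties, coefficients: dict | None = None
) -> VanGenuchtenParams:
    """Predict van Genuchten parameters for one layer.

    Requires sand, silt, clay, organic carbon, bulk density, CEC and pH-H2O.
    A negative predicted residual moisture is clamped to 0 with a warning
    (regression PTFs can emit slightly negative theta_r); a predicted shape
    parameter at or below 1 is clamped just above 1 the same way.
    """
    for name in _PTF_INPUTS:
        value = getattr(layer, name, None)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise EvaluationError(f"PTF input {name!r} is missing")
    coeffs = coefficients or load_ptf_coefficients()
    scale = float(coeffs["scale"])
    reg = _regressors(layer)

    def evaluate(term: str) -> float:
        terms = coeffs["terms"][term]
        return scale * sum(float(c) * reg[name] for name, c in terms.items())

    theta_s = evaluate("theta_s")
    theta_r = evaluate("theta_r")
    alpha = math.exp(evaluate("ln_alpha"))
    if coeffs.get("alpha_units", "per_cm") == "per_kPa":
        alpha /= KPA_TO_CM
    n = math.exp(evaluate("ln_n"))

    if theta_r < 0.0:
        logger.warning("PTF predicted theta_r=%.4f < 0; clamped to 0", theta_r)
        theta_r = 0.0
    if theta_s > 1.0:
        logger.warning("PTF predicted theta_s=%.4f > 1; clamped to 1", theta_s)
        theta_s = 1.0
    if theta_s <= theta_r:
        raise EvaluationError(
            f"PTF predicted theta_s={theta_s:.4f} <= theta_r={theta_r:.4f}"
        )
    if n <= 1.0:
        logger.warning("PTF predicted n=%.4f <= 1; clamped to 1.01", n)
        n = 1.01
    return VanGenuchtenParams(theta_r=theta_r, theta_s=theta_s, alpha=alpha, n=n)


def layer_retention(
    layer: LayerProperties,
    cfg: SuctionConfig | None = None,
    params: Optional[VanGenuchtenParams] = None,
    coefficients: dict | None = None,
) -> RetentionSummary:
    """Retention summary (v%) of one layer under the given FC definition.

    ``params`` injects van Genuchten parameters directly, bypassing the PTF
    (useful for testing and for sensitivity runs with measured retention).
    """
    cfg = cfg or SuctionConfig()
    if params is None:
        params = ptf_params(layer, coefficients=coefficients)
    sat = vg_theta(0.0, params)
    fc = vg_theta(cfg.fc_suction_cm, params)
    pwp = vg_theta(cfg.pwp_suction_cm, params)
    return RetentionSummary(
        vmc_sat=100.0 * sat, vmc_fc=100.0 * fc, vmc_pwp=100.0 * pwp
    )


def sfef(cf: float) -> float:
    """Soil fine earth fraction (0-1) from coarse fragments content (v%)."""
    if not 0.0 <= cf <= 100.0:
        raise ValidationError(f"coarse fragments must be in [0, 100] v%, got {cf}")
    return (100.0 - cf) / 100.0
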