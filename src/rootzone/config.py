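"""Run configuration.

The defaults reproduce the published evaluation set-up: field capacity at
pF 2.3, threshold rootability index 20%, maize maximum rooting depth 150 cm,
and a reference PAWHC of 10 v% for the unlimited member of the water
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError
from .hydrology import FC_SUCTION_CM


@dataclass
class RunConfig:
    fc_pf: float = 2.3
    threshold_index: float = 20.0
    max_crop_depth: float = 150.0
    reference_pawhc_v: float = 10.0
    rules_file: Optional[str] = None
    ptf_coefficients: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fc_pf not in FC_SUCTION_CM:
            raise ValidationError(
                f"fc_pf must be one of {sorted(FC_SUCTION_CM)}, got {self.fc_pf}"
            )
        if not 0.0 < self.threshold_index < 100.0:
            raise ValidationError("threshold_index must be in (0, 100)")
        if self.max_crop_depth <= 0:
            raise ValidationError("max_crop_depth must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)
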