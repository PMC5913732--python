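import numpy as np
import pytest
from hypothesis import settings

from rootzone import (
    DepthInterval,
    LayerProperties,
    ProfileMeta,
    RetentionSummary,
    STANDARD_INTERVALS,
    SoilProfile,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def benign_layer(**overrides) -> LayerProperties:
    """A mid-range tropical layer with nothing adverse."""
    base = dict(
        sand=40.0, silt=30.0, clay=30.0, oc=10.0, bd=1.3, cec=15.0, ph=6.5, cf=0.0
    )
    base.update(overrides)
    return LayerProperties(**base)


def benign_profile(profile_id="p1", drainage_class=5, depth_to_bedrock=None,
                   layer_overrides=None) -> SoilProfile:
    """Six standard intervals of benign layers; evaluates unrestricted.

    ``layer_overrides`` maps layer index -> dict of property overrides.
    """
    layer_overrides = layer_overrides or {}
    layers = [
        (interval, benign_layer(**layer_overrides.get(i, {})))
        for i, interval in enumerate(STANDARD_INTERVALS)
    ]
    return SoilProfile(
        meta=ProfileMeta(
            profile_id=profile_id,
            drainage_class=drainage_class,
            depth_to_bedrock=depth_to_bedrock,
        ),
        layers=layers,
    )


def flat_retention(n=6, vmc_sat=45.0, vmc_fc=25.0, vmc_pwp=15.0):
    """Injected retention: PAWHC fixed at vmc_fc - vmc_pwp v% in every layer."""
    return [RetentionSummary(vmc_sat, vmc_fc, vmc_pwp)] * n


@pytest.fixture
def unconstrained_profile():
    return benign_profile()


@pytest.fixture
def default_rules():
    from rootzone import load_rules

    return load_rules()
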