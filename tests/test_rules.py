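"""Rootability rules: breakpoints, derived variables, layer adequacy, depths."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rootzone import (
    DepthInterval,
    EvaluationError,
    STANDARD_INTERVALS,
    ValidationError,
    evaluate_layers,
    f_bd,
    f_exch_al,
    load_rules,
    restriction_depth,
    texture_change,
)

from conftest import benign_profile, flat_retention


def rule_by_name(rules, name):
    return next(r for r in rules if r.factor == name)


class TestEvalRule:
    def test_acidity_threshold_breakpoint(self, default_rules):
        acidity = rule_by_name(default_rules, "acidity_ph")
        assert acidity(4.0) == 20.0

    def test_acidity_interpolates_linearly(self, default_rules):
        acidity = rule_by_name(default_rules, "acidity_ph")
        assert acidity(4.5) == pytest.approx(20 + (4.5 - 4.0) / 1.5 * 80)

    def test_acidity_inversion_at_ri30(self, default_rules):
        acidity = rule_by_name(default_rules, "acidity_ph")
        assert acidity.invert(30.0) == pytest.approx(4.1875)

    def test_porosity_rule_at_threshold(self, default_rules):
        porosity = rule_by_name(default_rules, "porosity_vmc_sat")
        assert porosity(30.0) == 20.0

    def test_constant_beyond_outer_breakpoints(self, default_rules):
        sodicity = rule_by_name(default_rules, "sodicity_exch_na")
        assert sodicity(0.0) == 100.0
        assert sodicity(50.0) == 0.0

    @given(value=st.floats(-50.0, 200.0))
    def test_output_bounded(self, value):
        for rule in load_rules():
            assert 0.0 <= rule(value) <= 100.0

    def test_monotone_between_breakpoints(self, default_rules):
        for rule in default_rules:
            xs = np.array([v for v, _ in rule.points])
            ris = np.array([ri for _, ri in rule.points])
            grid = np.linspace(xs[0], xs[-1], 500)
            out = rule(grid)
            # RI is monotone within each breakpoint segment
            for (a, ra), (b, rb) in zip(rule.points, rule.points[1:]):
                seg = out[(grid >= a) & (grid <= b)]
                diffs = np.diff(seg)
                assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)

    def test_threshold_value_property(self, default_rules):
        assert rule_by_name(default_rules, "acidity_ph").threshold_value == 4.0
        assert rule_by_name(default_rules, "sodicity_exch_na").threshold_value == 4.2


class TestDerivedVariables:
    def test_critical_bd_pure_clay(self):
        assert f_bd(1.25, 100.0) == pytest.approx(0.0)

    def test_critical_bd_pure_sand(self):
        assert f_bd(1.60, 0.0) == pytest.approx(0.0)

    def test_dense_sand_fully_restrictive(self, default_rules):
        value = f_bd(1.90, 0.0)
        assert value == pytest.approx(0.30)
        assert rule_by_name(default_rules, "porosity_f_bd")(value) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_aluminium_saturation(self, default_rules):
        rule = rule_by_name(default_rules, "toxicity_f_exch_al")
        assert f_exch_al(3.0, 10.0) == pytest.approx(30.0)
        assert rule(f_exch_al(3.0, 10.0)) == 100.0
        assert f_exch_al(0.0, 10.0) == 0.0
        assert rule(f_exch_al(7.5, 10.0)) == 20.0

    def test_aluminium_saturation_clamped_and_undefined(self):
        assert f_exch_al(25.0, 10.0) == 100.0
        with pytest.raises(EvaluationError):
            f_exch_al(1.0, 0.0)

    def test_texture_change_assigned_to_deeper_interval(self, default_rules):
        profile = benign_profile(
            layer_overrides={
                3: dict(sand=95.0, silt=5.0, clay=0.0),
            }
        )
        d_sand, _ = texture_change(profile)
        assert d_sand[0] == 0.0
        assert d_sand[3] == pytest.approx(55.0)
        assert rule_by_name(default_rules, "texture_d_sand")(d_sand[3]) == 0.0

    def test_uniform_texture_no_change(self, default_rules):
        d_sand, d_clay = texture_change(benign_profile())
        assert np.allclose(d_sand, 0.0) and np.allclose(d_clay, 0.0)
        assert rule_by_name(default_rules, "texture_d_sand")(0.0) == 100.0

    def test_clay_increase_at_last_adequate_breakpoint(self, default_rules):
        profile = benign_profile(
            layer_overrides={
                0: dict(clay=10.0, sand=60.0),
                1: dict(clay=10.0, sand=60.0),
                2: dict(clay=40.0, sand=30.0),
            }
        )
        _, d_clay = texture_change(profile)
        assert d_clay[2] == pytest.approx(30.0)
        assert rule_by_name(default_rules, "texture_d_clay")(d_clay[2]) == 100.0


class TestEvaluateLayers:
    def test_benign_profile_fully_adequate(self, unconstrained_profile):
        ev = evaluate_layers(unconstrained_profile, flat_retention())
        assert ev.adequate.all()
        for name in ("acidity_ph", "alkalinity_ph", "porosity_vmc_sat"):
            assert np.nanmin(ev.factor_ri[name]) == 100.0

    def test_sodic_layer_inadequate(self):
        profile = benign_profile(layer_overrides={3: dict(exch_na=5.0)})
        ev = evaluate_layers(profile, flat_retention())
        assert ev.factor_ri["sodicity_exch_na"][3] == 0.0
        assert not ev.adequate[3]
        assert ev.adequate[[0, 1, 2, 4, 5]].all()

    def test_mildly_acid_layer_still_adequate(self):
        profile = benign_profile(layer_overrides={2: dict(ph=4.5)})
        ev = evaluate_layers(profile, flat_retention())
        assert ev.factor_ri["acidity_ph"][2] == pytest.approx(46.6667, abs=1e-3)
        assert ev.adequate[2]

    def test_unmeasured_factors_skipped_not_zero(self, unconstrained_profile):
        # benign fixture has no chemistry -> those factors must be skipped
        ev = evaluate_layers(unconstrained_profile, flat_retention())
        assert "salinity_ec" in ev.skipped
        assert np.isnan(ev.factor_ri["salinity_ec"]).all()
        assert ev.adequate.all()

    def test_adequate_exactly_at_threshold(self):
        # restriction requires RI strictly below the threshold index
        profile = benign_profile(layer_overrides={4: dict(exch_na=4.2)})
        ev = evaluate_layers(profile, flat_retention())
        assert ev.factor_ri["sodicity_exch_na"][4] == 20.0
        assert ev.adequate[4]


class TestRestrictionDepth:
    def test_never_restricted(self):
        assert restriction_depth([100] * 6, STANDARD_INTERVALS, 20.0) is None

    def test_restricted_from_surface(self):
        assert restriction_depth([0, 100, 100, 100, 100, 100], STANDARD_INTERVALS, 20.0) == 0.0

    def test_linear_crossing_between_midpoints(self):
        # frozen hand calculation: 45 + (50-20)/(50-10)*35 = 71.25 cm
        depth = restriction_depth(
            [100, 100, 100, 50, 10, 10], STANDARD_INTERVALS, 20.0
        )
        assert depth == pytest.approx(71.25)

    def test_nan_intervals_excluded(self):
        depth = restriction_depth(
            [100, np.nan, 100, 50, 10, 10], STANDARD_INTERVALS, 20.0
        )
        assert depth == pytest.approx(71.25)

    def test_all_nan_returns_none(self):
        assert restriction_depth([np.nan] * 6, STANDARD_INTERVALS, 20.0) is None
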