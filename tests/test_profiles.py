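"""Domain type validation and tabular round trips."""

import math

import pandas as pd
import pytest

from rootzone import (
    DepthInterval,
    LayerProperties,
    ProfileMeta,
    SchemaError,
    SoilProfile,
    ValidationError,
    read_profiles,
    write_profiles,
    write_results,
)
from rootzone.profiles import profiles_to_frame

from conftest import benign_layer, benign_profile, flat_retention


class TestDomainTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValidationError):
            DepthInterval(10, 10)
        with pytest.raises(ValidationError):
            DepthInterval(-5, 10)
        assert DepthInterval(30, 60).midpoint == 45.0

    def test_texture_must_sum_to_100(self):
        with pytest.raises(ValidationError, match="sand\\+silt\\+clay"):
            benign_layer(sand=50.0, silt=30.0, clay=30.0)

    def test_required_property_cannot_be_missing(self):
        with pytest.raises(ValidationError, match="bd"):
            benign_layer(bd=float("nan"))

    def test_optional_nan_normalised_to_none(self):
        layer = benign_layer(ec=float("nan"))
        assert layer.ec is None

    def test_negative_chemistry_rejected(self):
        with pytest.raises(ValidationError):
            benign_layer(exch_na=-0.1)

    def test_drainage_class_range(self):
        with pytest.raises(ValidationError):
            ProfileMeta(profile_id="x", drainage_class=8)

    def test_layers_resorted_by_top_depth(self):
        layers = benign_profile().layers
        profile = SoilProfile(
            meta=ProfileMeta(profile_id="x"), layers=list(reversed(layers))
        )
        tops = [iv.top for iv in profile.intervals]
        assert tops == sorted(tops) and tops[0] == 0.0

    def test_non_contiguous_intervals_rejected_naming_profile(self):
        with pytest.raises(ValidationError, match="gap1"):
            SoilProfile(
                meta=ProfileMeta(profile_id="gap1"),
                layers=[
                    (DepthInterval(0, 10), benign_layer()),
                    (DepthInterval(20, 30), benign_layer()),
                ],
            )

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValidationError):
            SoilProfile(
                meta=ProfileMeta(profile_id="ovl"),
                layers=[
                    (DepthInterval(0, 10), benign_layer()),
                    (DepthInterval(5, 15), benign_layer()),
                ],
            )


class TestTabularIO:
    def test_round_trip_lossless(self, tmp_path):
        profiles = [
            benign_profile("a", drainage_class=4, depth_to_bedrock=90.0),
            benign_profile(
                "b", layer_overrides={2: dict(ec=1.2, exch_na=0.4, caco3=55.0)}
            ),
        ]
        path = tmp_path / "profiles.csv"
        write_profiles(profiles, path)
        back = read_profiles(path)
        assert profiles_to_frame(back).equals(profiles_to_frame(profiles))

    def test_rows_out_of_order_resorted(self, tmp_path):
        df = profiles_to_frame([benign_profile()])
        df = df.iloc[::-1]  # deepest interval first
        path = tmp_path / "shuffled.csv"
        df.to_csv(path, index=False)
        (profile,) = read_profiles(path)
        assert [iv.top for iv in profile.intervals] == [0, 5, 15, 30, 60, 100]

    def test_overlapping_intervals_error_names_profile(self, tmp_path):
        df = profiles_to_frame([benign_profile("bad")])
        df.loc[1, "top"] = 3.0  # second interval now overlaps the first
        path = tmp_path / "overlap.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="bad"):
            read_profiles(path)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        df = profiles_to_frame([benign_profile()]).drop(columns=["bd"])
        path = tmp_path / "nobd.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="bd"):
            read_profiles(path)

    def test_schema_mapping_renames_columns(self, tmp_path):
        df = profiles_to_frame([benign_profile()]).rename(
            columns={"bd": "bulk_density", "profile_id": "pid"}
        )
        path = tmp_path / "mapped.csv"
        df.to_csv(path, index=False)
        (profile,) = read_profiles(
            path, schema={"bd": "bulk_density", "profile_id": "pid"}
        )
        assert profile.properties[0].bd == pytest.approx(1.3)

    def test_missing_optional_read_as_none(self, tmp_path):
        df = profiles_to_frame([benign_profile()]).drop(columns=["ec"])
        path = tmp_path / "noec.csv"
        df.to_csv(path, index=False)
        (profile,) = read_profiles(path)
        assert all(p.ec is None for p in profile.properties)


class TestWriteResults:
    def _reports(self, n=3):
        from rootzone import RunConfig, evaluate_profile

        return [
            evaluate_profile(
                benign_profile(f"p{i}"),
                config=RunConfig(),
                retention=flat_retention(),
            )
            for i in range(n)
        ]

    def test_one_row_per_profile_round_trip(self, tmp_path):
        reports = self._reports(3)
        path = tmp_path / "results.csv"
        write_results(reports, path)
        df = pd.read_csv(path)
        assert len(df) == 3
        assert list(df.columns) == [
            "profile_id", "rzd_cm", "limiting_factor", "rz_pawhc_mm"
        ]
        assert (df["rzd_cm"] == 150.0).all()

    def test_unrestricted_row_values(self, tmp_path):
        path = tmp_path / "row.csv"
        write_results(self._reports(1), path)
        row = pd.read_csv(path).iloc[0]
        assert row["rzd_cm"] == 150.0
        assert row["limiting_factor"] == "unrestricted"
        assert row["rz_pawhc_mm"] == 150.0

    def test_empty_results_error_and_no_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        with pytest.raises(ValidationError):
            write_results([], path)
        assert not path.exists()
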