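"""Localization I/O, re-blink linking, and channel-transform fitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from oracles import brute_link

from nanoorg import locio
from nanoorg.exceptions import (DegeneracyError, ParameterError, ParseError,
                                SchemaError)


class TestReadWrite:
    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "locs.csv"
        path.write_text(
            "frame,x_nm,y_nm,photons,precision_nm\n"
            "0,100.5,200.25,1500,8.2\n"
            "1,110.0,205.0,900,12.0\n"
            "4,50.0,60.0,2000,9.1\n")
        table = locio.read_locs(path)
        assert len(table) == 3
        assert table.df.loc[0, "x"] == 100.5
        out = tmp_path / "out.csv"
        locio.write_locs(table, out)
        again = locio.read_locs(out)
        pd.testing.assert_frame_equal(table.df, again.df)

    def test_empty_file_with_headers(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("frame,x_nm,y_nm,photons,precision_nm\n")
        assert len(locio.read_locs(path)) == 0

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,x_nm,photons,precision_nm\n0,1.0,10,5.0\n")
        with pytest.raises(SchemaError, match="y_nm"):
            locio.read_locs(path)

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,x_nm,y_nm,photons,precision_nm\n"
                        "0,1.0,2.0,10,5.0\n0,oops,2.0,10,5.0\n")
        with pytest.raises(ParseError, match="row 1"):
            locio.read_locs(path)

    def test_hdf5_roundtrip(self, tmp_path):
        table = make_table([[1.0, 2.0], [3.0, 4.0]], frames=[0, 5],
                           channel_label="gephyrin")
        path = tmp_path / "locs.h5"
        locio.write_locs(table, path)
        again = locio.read_locs(path, channel_label="gephyrin")
        np.testing.assert_allclose(again.xy, table.xy)
        assert again.channel_label == "gephyrin"

    def test_extra_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text("frame,x_nm,y_nm,photons,precision_nm,sigma\n"
                        "0,1.0,2.0,10,5.0,1.3\n")
        table = locio.read_locs(path)
        assert "sigma" in table.df.columns


class TestLinkConsecutive:
    def test_coincident_consecutive_frames_merge(self):
        table = make_table([[100.0, 100.0], [100.0, 100.0]], frames=[5, 6],
                           photons=[100.0, 300.0], n_frames=10)
        linked = locio.link_consecutive(table, radius=20.0)
        assert len(linked) == 1
        row = linked.df.iloc[0]
        assert row["frame"] == 5
        assert row["photons"] == 400.0

    def test_distant_points_retained(self):
        table = make_table([[0.0, 0.0], [500.0, 0.0]], frames=[5, 6], n_frames=10)
        assert len(locio.link_consecutive(table, radius=20.0)) == 2

    def test_same_frame_never_linked(self):
        table = make_table([[0.0, 0.0], [1.0, 0.0]], frames=[3, 3], n_frames=10)
        assert len(locio.link_consecutive(table, radius=20.0)) == 2

    def test_merge_is_photon_weighted(self):
        table = make_table([[0.0, 0.0], [10.0, 0.0]], frames=[0, 1],
                           photons=[100.0, 300.0], n_frames=5)
        linked = locio.link_consecutive(table, radius=20.0)
        assert linked.df.loc[0, "x"] == pytest.approx(7.5)

    @pytest.mark.parametrize("max_gap", [0, 1])
    def test_matches_chain_following_oracle(self, max_gap):
        rng = np.random.default_rng(17)
        n = 200
        xy = rng.uniform(0, 1000, (n, 2))
        frames = rng.integers(0, 40, n)
        photons = rng.integers(100, 3000, n).astype(float)
        table = make_table(xy, frames=frames, photons=photons, n_frames=40)
        linked = locio.link_consecutive(table, radius=30.0, max_gap=max_gap)

        df = table.df  # table sorts rows, so feed the oracle the same order
        expected = brute_link(df["frame"].to_numpy(), df[["x", "y"]].to_numpy(),
                              df["photons"].to_numpy(), df["precision"].to_numpy(),
                              radius=30.0, max_gap=max_gap)
        got = np.array(sorted(zip(linked.df["frame"], linked.df["x"],
                                  linked.df["y"], linked.df["photons"],
                                  linked.df["precision"])))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_idempotent_on_seeded_field(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.uniform(0, 5000, (300, 2)),
                           frames=rng.integers(0, 100, 300), n_frames=100)
        once = locio.link_consecutive(table, radius=30.0)
        twice = locio.link_consecutive(once, radius=30.0)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_zero_radius_is_identity(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.uniform(0, 500, (50, 2)),
                           frames=rng.integers(0, 10, 50), n_frames=10)
        linked = locio.link_consecutive(table, radius=0.0)
        pd.testing.assert_frame_equal(linked.df, table.df)

    def test_negative_radius_rejected(self):
        table = make_table([[0.0, 0.0]])
        with pytest.raises(ParameterError):
            locio.link_consecutive(table, radius=-1.0)

    def test_output_never_larger_than_input(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.uniform(0, 300, (150, 2)),
                           frames=rng.integers(0, 20, 150), n_frames=20)
        assert len(locio.link_consecutive(table, radius=50.0)) <= len(table)


class TestChannelTransform:
    def test_identity_from_identical_beads(self):
        beads = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [70.0, 30.0]])
        t = locio.fit_channel_transform(beads, beads, "affine")
        np.testing.assert_allclose(t.matrix, np.column_stack([np.eye(2), [0, 0]]),
                                   atol=1e-9)
        assert t.residual_rmse == pytest.approx(0.0, abs=1e-9)

    def test_exact_translation_recovered(self):
        ref = np.array([[0.0, 0.0], [50.0, 80.0], [200.0, 10.0]])
        t = locio.fit_channel_transform(ref, ref + [12.5, -7.0], "translation")
        np.testing.assert_allclose(t.parameters, [12.5, -7.0])
        assert t.residual_rmse == pytest.approx(0.0, abs=1e-9)

    def test_affine_recovery_under_jitter(self):
        rng = np.random.default_rng(11)
        truth = np.array([[1.001, 0.02, 12.0], [-0.015, 0.998, -7.5]])
        ref = rng.uniform(0, 20000, (10, 2))
        mov = ref @ truth[:, :2].T + truth[:, 2] + rng.normal(0, 1.0, (10, 2))
        t = locio.fit_channel_transform(ref, mov, "affine")
        # closed-form least squares is the oracle; coefficients near truth
        np.testing.assert_allclose(t.matrix[:, :2], truth[:, :2], atol=5e-4)
        np.testing.assert_allclose(t.matrix[:, 2], truth[:, 2], atol=6.0)
        assert t.residual_rmse < 3.0

    def test_collinear_beads_degenerate(self):
        ref = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(DegeneracyError):
            locio.fit_channel_transform(ref, ref + 5.0, "affine")

    def test_apply_identity_and_translation(self):
        table = make_table([[0.0, 0.0], [5.0, 5.0]])
        ident = locio.ChannelTransform("affine",
                                       np.column_stack([np.eye(2), [0, 0]]), 0.0)
        np.testing.assert_allclose(locio.apply_transform(table, ident).xy, table.xy)
        shift = locio.ChannelTransform("translation",
                                       np.column_stack([np.eye(2), [10, 0]]), 0.0)
        np.testing.assert_allclose(locio.apply_transform(table, shift).xy[0], [10, 0])

    def test_affine_round_trip(self):
        rng = np.random.default_rng(12)
        ref = rng.uniform(0, 1000, (8, 2))
        mov = ref @ np.array([[1.01, 0.03], [-0.02, 0.99]]).T + [15.0, -4.0]
        t = locio.fit_channel_transform(ref, mov, "affine")
        table = make_table(rng.uniform(0, 1000, (20, 2)))
        back = locio.apply_transform(locio.apply_transform(table, t), t.inverse())
        np.testing.assert_allclose(back.xy, table.xy, atol=1e-9)

    def test_transform_json_roundtrip(self):
        t = locio.fit_channel_transform([[0, 0], [1, 5]], [[2, 1], [3, 6]],
                                        "translation")
        t2 = locio.ChannelTransform.from_dict(t.to_dict())
        np.testing.assert_allclose(t.matrix, t2.matrix)
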