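"""Trace discretization: heading, acceleration, encoding, inactive splits."""

import math

import numpy as np
import pytest

from movemine import (
    GpsFix,
    GpsTrace,
    MovementDiscretizer,
    derive_acceleration,
    discretize_trace,
    heading_change,
    read_gps_csv,
    split_inactive,
    write_gps_csv,
)
from movemine.discretize import read_sequences, write_sequences

from conftest import TABLE1_STRING, table1_trace


def _fix(t, lat, lon, v=1.0):
    return GpsFix(time_s=t, velocity=v, latitude=lat, longitude=lon)


class TestHeadingChange:
    def test_collinear_points_give_zero(self):
        a = _fix(0.0, 53.0, -1.5)
        b = _fix(0.1, 53.00001, -1.5)
        c = _fix(0.2, 53.00002, -1.5)
        assert heading_change(a, b, c) == pytest.approx(0.0, abs=1e-9)

    def test_path_reversal_gives_180(self):
        a = _fix(0.0, 53.0, -1.5)
        b = _fix(0.1, 53.00001, -1.5)
        assert heading_change(a, b, a) == pytest.approx(180.0, abs=1e-9)

    def test_right_angle_corner(self):
        # East then north on a small local grid; independent spherical
        # initial-bearing computation puts the change at 90 degrees.
        lat0, lon0 = 53.0, -1.5
        dlon = 1.0 / (111_320.0 * math.cos(math.radians(lat0)))
        dlat = 1.0 / 111_320.0
        a = _fix(0.0, lat0, lon0)
        b = _fix(0.1, lat0, lon0 + dlon)
        c = _fix(0.2, lat0 + dlat, lon0 + dlon)
        assert heading_change(a, b, c) == pytest.approx(90.0, abs=0.5)

    def test_sub_epsilon_motion_returns_zero(self):
        a = _fix(0.0, 53.0, -1.5)
        c = _fix(0.2, 53.00001, -1.5)
        assert heading_change(a, a, c) == 0.0

    def test_missing_coordinates_rejected(self):
        a = GpsFix(time_s=0.0, velocity=1.0, turning_angle=0.0)
        b = _fix(0.1, 53.0, -1.5)
        with pytest.raises(ValueError):
            heading_change(a, b, b)


class TestDeriveAcceleration:
    def test_constant_velocity_gives_zeros(self):
        tr = GpsTrace("p", "m", "hooker", [
            GpsFix(time_s=0.1 * i, velocity=2.0, turning_angle=0.0) for i in range(20)
        ])
        assert np.allclose(derive_acceleration(tr), 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        tr = GpsTrace("p", "m", "hooker", [
            GpsFix(time_s=0.1 * i, velocity=0.1 * i, turning_angle=0.0)
            for i in range(11)
        ])
        acc = derive_acceleration(tr)
        assert np.allclose(acc, 1.0)

    def test_matches_brute_force_finite_differences(self, rng):
        v = rng.uniform(0, 8, 50)
        tr = GpsTrace("p", "m", "hooker", [
            GpsFix(time_s=0.1 * i, velocity=v[i], turning_angle=0.0)
            for i in range(50)
        ])
        acc = derive_acceleration(tr)
        expected = np.empty(50)
        expected[0] = (v[1] - v[0]) / 0.1
        expected[-1] = (v[-1] - v[-2]) / 0.1
        for i in range(1, 49):
            expected[i] = (v[i + 1] - v[i - 1]) / 0.2
        assert np.allclose(acc, expected)

    def test_single_fix_rejected(self):
        tr = GpsTrace("p", "m", "hooker", [GpsFix(time_s=0.0, velocity=1.0, turning_angle=0.0)])
        with pytest.raises(ValueError):
            derive_acceleration(tr)


class TestDiscretizeTrace:
    def test_worked_example_encodes_exactly(self):
        assert discretize_trace(table1_trace()) == TABLE1_STRING

    def test_length_equals_trace_length(self, rng):
        n = 200
        tr = GpsTrace("p", "m", "winger", [
            GpsFix(time_s=0.1 * i, velocity=rng.uniform(0, 8),
                   acceleration=rng.uniform(-3, 3),
                   turning_angle=rng.uniform(0, 180))
            for i in range(n)
        ])
        assert len(discretize_trace(tr)) == n

    def test_constant_walk_neutral_straight_is_all_e(self):
        tr = GpsTrace("p", "m", "hooker", [
            GpsFix(time_s=0.1 * i, velocity=1.0, turning_angle=0.0)
            for i in range(30)
        ])
        # Constant velocity -> zero derived acceleration -> Neutral band.
        assert discretize_trace(tr) == "e" * 30


class TestSplitInactive:
    def test_no_subthreshold_run_keeps_whole_sequence(self):
        seqs = split_inactive("e" * 50, np.full(50, 1.0))
        assert len(seqs) == 1 and seqs[0].symbols == "e" * 50

    def test_entirely_inactive_trace_yields_nothing(self):
        assert split_inactive("e" * 50, np.full(50, 0.05)) == []

    def test_planted_gap_splits_and_deletes_exactly(self):
        # 40 active + 30 inactive (3 s at v=0.1) + 50 active.
        symbols = "a" * 40 + "b" * 30 + "c" * 50
        vel = np.concatenate([np.full(40, 1.0), np.full(30, 0.1), np.full(50, 1.0)])
        seqs = split_inactive(symbols, vel, v_min=0.2, t_min=2.0)
        assert [s.symbols for s in seqs] == ["a" * 40, "c" * 50]
        assert [s.segment_index for s in seqs] == [0, 1]
        assert sum(len(s) for s in seqs) == len(symbols) - 30

    def test_short_subthreshold_run_is_kept_in_place(self):
        symbols = "a" * 10 + "b" * 10 + "c" * 10
        vel = np.concatenate([np.full(10, 1.0), np.full(10, 0.1), np.full(10, 1.0)])
        seqs = split_inactive(symbols, vel, v_min=0.2, t_min=2.0)
        assert len(seqs) == 1 and seqs[0].symbols == symbols

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_inactive("abc", [1.0, 1.0])


class TestIoRoundTrips:
    def test_gps_csv_round_trip(self, tmp_path, rng):
        tr = table1_trace()
        path = tmp_path / "gps.csv"
        write_gps_csv([tr], path)
        back = read_gps_csv(path)
        assert len(back) == 1
        assert discretize_trace(back[0]) == TABLE1_STRING
        assert back[0].position == "hooker"

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,velocity\n0.0,1.0\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_gps_csv(path)

    def test_sequence_file_round_trip(self, tmp_path):
        disc = MovementDiscretizer()
        corpora = disc.fit([table1_trace()]).transform([table1_trace()])
        path = tmp_path / "seqs.tsv"
        write_sequences(corpora, path)
        back = read_sequences(path)
        assert [c.symbols for c in back] == [c.symbols for c in corpora]


def test_discretizer_is_sklearn_compatible():
    disc = MovementDiscretizer(v_min=0.3)
    assert disc.get_params()["v_min"] == 0.3
    disc.set_params(t_min=1.5)
    out = disc.fit([table1_trace()]).transform([table1_trace()])
    assert len(out) == 1 and out[0].symbols == [TABLE1_STRING]
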