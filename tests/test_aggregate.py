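"""Seasonal split, night assignment, nightly series, trends, profiles, maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from birdwind import (
    RadarMetadata,
    add_night_ids,
    assign_night,
    assign_season,
    experienced_vs_available,
    monthly_trend,
    moving_average,
    nightly_series,
    spatial_summary,
)
from birdwind.aggregate import DAYS_PER_MONTH, altitude_profile, default_periods
from tests.conftest import make_profile_frame


class TestAssignSeason:
    @pytest.mark.parametrize(
        "ts, expected",
        [
            ("2018-04-01", "spring"),
            ("2018-10-15", "autumn"),
            ("2018-07-15T00:00:00", "autumn"),  # cutoff day itself is autumn
            ("2018-07-14T23:59:59", "spring"),
        ],
    )
    def test_cutoff_rule(self, ts, expected):
        assert assign_season([ts])[0] == expected

    def test_custom_cutoff(self):
        assert assign_season(["2018-07-15"], cutoff="08-01")[0] == "spring"


class TestAssignNight:
    RADAR = RadarMetadata("r0", 47.0, 5.0)

    def test_night_straddles_midnight(self):
        nid, night = assign_night(["2018-04-01 22:00", "2018-04-02 01:00"], self.RADAR)
        assert night.all()
        assert nid[0] == nid[1] == np.datetime64("2018-04-01")

    def test_local_noon_excluded(self):
        _, night = assign_night(["2018-04-01 12:00"], self.RADAR)
        assert not night.any()

    def test_synthetic_night_only_data_has_zero_exclusions(
        self, small_kinematics, small_network
    ):
        res = add_night_ids(small_kinematics, small_network)
        assert res.n_excluded == 0
        assert len(res.records) == len(small_kinematics)


def _kin_frame(rows):
    df = make_profile_frame(rows)
    for col, default in (("U", 0.0), ("V", 0.0)):
        if col not in df:
            df[col] = default
    df["Vg"] = np.hypot(df["u"], df["v"])
    df["Va"] = np.hypot(df["u"] - df["U"], df["v"] - df["V"])
    df["W"] = np.hypot(df["U"], df["V"])
    df["wp"] = 0.0
    df["season"] = assign_season(df["datetime"])
    df["night_id"] = pd.DatetimeIndex(df["datetime"]).normalize()
    return df


class TestNightlySeries:
    def test_single_record_night_returns_its_values(self):
        df = _kin_frame([{"datetime": "2018-04-01 22:00", "height": 300.0, "u": 3.0, "v": 4.0}])
        ns = nightly_series(df)
        assert len(ns) == 1
        assert ns["Vg"].iloc[0] == pytest.approx(5.0)
        assert ns["n_records"].iloc[0] == 1

    def test_equal_densities_give_unweighted_means(self):
        df = _kin_frame(
            [
                {"datetime": "2018-04-01 22:00", "height": 300.0, "u": 3.0, "v": 4.0, "dens": 2.0},
                {"datetime": "2018-04-01 23:00", "height": 300.0, "u": 6.0, "v": 8.0, "dens": 2.0},
            ]
        )
        ns = nightly_series(df)
        assert ns["Vg"].iloc[0] == pytest.approx(7.5)

    def test_density_weighting(self):
        df = _kin_frame(
            [
                {"datetime": "2018-04-01 22:00", "height": 300.0, "u": 0.0, "v": 8.0, "dens": 1.0},
                {"datetime": "2018-04-01 23:00", "height": 300.0, "u": 0.0, "v": 10.0, "dens": 3.0},
            ]
        )
        assert nightly_series(df)["Vg"].iloc[0] == pytest.approx(9.5)


class TestMovingAverage:
    def _series(self, values, start="2018-04-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.Series(values, index=idx, dtype=float)

    def test_constant_series_unchanged(self):
        s = self._series([4.0] * 10)
        pd.testing.assert_series_equal(moving_average(s, 7), s)

    def test_center_of_1_to_7_is_4(self):
        s = self._series([1, 2, 3, 4, 5, 6, 7])
        assert moving_average(s, 7).iloc[3] == pytest.approx(4.0)

    def test_edge_window_shrinks(self):
        s = self._series([1, 2, 3, 4, 5, 6, 7])
        # at the first night only nights 1..4 fall inside the centered window
        assert moving_average(s, 7).iloc[0] == pytest.approx(np.mean([1, 2, 3, 4]))

    def test_missing_nights_skipped_not_zero_filled(self):
        s = self._series([1, 2, 3, 4, 5, 6, 7])
        gappy = s.drop(s.index[2])
        out = moving_average(gappy, 7)
        assert out.iloc[2] == pytest.approx(np.mean([1, 2, 4, 5, 6, 7]))

    def test_commutes_with_adding_constant(self):
        s = self._series([1, 5, 2, 8, 3, 9, 4])
        np.testing.assert_allclose(moving_average(s + 10, 7), moving_average(s, 7) + 10)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(self._series([1, 2, 3]), 4)


def _nightly(dates, y, w):
    return pd.DataFrame(
        {"Va": y, "Vg": y, "W": y, "wp": y, "total_density": w, "n_records": 1},
        index=pd.DatetimeIndex(dates, name="night_id"),
    )


class TestMonthlyTrend:
    def test_noiseless_line_recovered_exactly(self):
        dates = pd.date_range("2018-03-01", periods=30, freq="D")
        t_months = np.arange(30) / DAYS_PER_MONTH
        y = 10.0 - 2.0 * t_months
        tr = monthly_trend(_nightly(dates, y, np.ones(30)), "Va")
        assert tr.slope == pytest.approx(-2.0, abs=1e-9)
        assert tr.ci_high - tr.ci_low == pytest.approx(0.0, abs=1e-6)
        assert tr.n_nights == 30

    def test_reversed_time_negates_slope(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("2018-03-01", periods=40, freq="D")
        y = 8.0 + 0.7 * np.arange(40) / DAYS_PER_MONTH + rng.normal(0, 0.3, 40)
        fwd = monthly_trend(_nightly(dates, y, np.ones(40)), "Va")
        rev = monthly_trend(_nightly(dates, y[::-1], np.ones(40)), "Va")
        assert rev.slope == pytest.approx(-fwd.slope, abs=1e-9)

    def test_dominant_weight_pulls_fit(self):
        dates = pd.date_range("2018-03-01", periods=3, freq="D")
        y = np.array([10.0, 0.0, 12.0])
        w = np.array([1e6, 1e-6, 1e6])
        tr = monthly_trend(_nightly(dates, y, w), "Va")
        # the near-zero-weight middle point barely moves the line through (10, 12)
        expected = (12.0 - 10.0) / (2.0 / DAYS_PER_MONTH)
        assert tr.slope == pytest.approx(expected, rel=1e-3)

    def test_too_few_nights_error(self):
        dates = pd.date_range("2018-03-01", periods=2, freq="D")
        with pytest.raises(ValueError, match="3 nights"):
            monthly_trend(_nightly(dates, [1.0, 2.0], [1.0, 1.0]), "Va")

    def test_season_filter(self):
        dates = pd.date_range("2018-07-10", periods=10, freq="D")
        y = np.arange(10, dtype=float)
        tr = monthly_trend(_nightly(dates, y, np.ones(10)), "Va", season="autumn")
        assert tr.n_nights == 5  # Jul-15 onward


class TestAltitudeProfile:
    def test_record_binning_and_single_bin(self):
        df = _kin_frame(
            [{"datetime": "2018-04-01 22:00", "height": 300.0, "u": 3.0, "v": 4.0}]
        )
        prof = altitude_profile(df)
        assert len(prof) == 1
        assert prof["height"].iloc[0] == 300.0
        assert prof["ground_speed"].iloc[0] == pytest.approx(5.0)

    def test_flat_airspeed_profile_under_shear(self, small_kinematics):
        prof = altitude_profile(small_kinematics, season="spring")
        prof = prof[prof["total_density"] > prof["total_density"].sum() * 0.01]
        # wind increases with altitude by construction; airspeed does not
        wind_range = prof["wind_speed"].max() - prof["wind_speed"].min()
        air_range = prof["Va_mean"].max() - prof["Va_mean"].min()
        assert wind_range > 1.0
        assert air_range < wind_range / 2


class TestSpatialSummary:
    def test_identical_records_return_that_vector(self):
        df = _kin_frame(
            [
                {"datetime": "2018-04-01 22:00", "height": 300.0, "u": 3.0, "v": 4.0},
                {"datetime": "2018-04-02 22:00", "height": 300.0, "u": 3.0, "v": 4.0},
            ]
        )
        out = spatial_summary(df, default_periods(2018))
        assert len(out) == 1
        assert out["ground_speed"].iloc[0] == pytest.approx(5.0)
        assert out["ground_bearing"].iloc[0] == pytest.approx(np.degrees(np.arctan2(3, 4)))

    def test_opposite_vectors_cancel(self):
        df = _kin_frame(
            [
                {"datetime": "2018-04-01 22:00", "height": 300.0, "u": 1.0, "v": 0.0},
                {"datetime": "2018-04-02 22:00", "height": 300.0, "u": -1.0, "v": 0.0},
            ]
        )
        out = spatial_summary(df, default_periods(2018))
        assert out["ground_speed"].iloc[0] == pytest.approx(0.0)

    def test_overlapping_periods_fatal(self):
        df = _kin_frame(
            [{"datetime": "2018-04-01 22:00", "height": 300.0, "u": 1.0, "v": 0.0}]
        )
        periods = [("a", "2018-02-01", "2018-05-01"), ("b", "2018-04-15", "2018-06-01")]
        with pytest.raises(ValueError, match="overlap"):
            spatial_summary(df, periods)

    def test_each_record_in_at_most_one_period(self, small_kinematics):
        periods = default_periods(2018)
        out = spatial_summary(small_kinematics, periods)
        assert out["n_records"].sum() <= len(small_kinematics)
        assert set(out["period"]) <= {p[0] for p in periods}

    def test_wind_map_reproduces_generator_field(self, small_kinematics, small_sim):
        _, truth = small_sim
        out = spatial_summary(small_kinematics, default_periods(2018))
        # density-weighted truth wind per radar must match the map's wind average
        merged = small_kinematics.assign(Ut=truth["U"].to_numpy(), Vt=truth["V"].to_numpy())
        for row in out.itertuples():
            sub = merged[merged["radar"] == row.radar]
            w = sub["dens"].to_numpy()
            assert row.wind_u == pytest.approx(np.average(sub["Ut"], weights=w), abs=1e-9)
            assert row.wind_v == pytest.approx(np.average(sub["Vt"], weights=w), abs=1e-9)


class TestExperiencedVsAvailable:
    def test_uniform_density_makes_them_equal(self):
        df = _kin_frame(
            [
                {"datetime": "2018-04-01 22:00", "height": 300.0, "u": 1.0, "v": 0.0},
                {"datetime": "2018-04-01 23:00", "height": 300.0, "u": 2.0, "v": 0.0},
            ]
        )
        df["W"] = [5.0, 7.0]
        df["wp"] = [1.0, 3.0]
        exp = experienced_vs_available(df)
        assert exp.experienced_W.mean == pytest.approx(exp.available_W.mean)
        assert exp.experienced_wp.mean == pytest.approx(exp.available_wp.mean)

    def test_density_on_high_wp_records_raises_experienced(self):
        df = _kin_frame(
            [
                {"datetime": "2018-04-01 22:00", "height": 300.0, "u": 1.0, "v": 0.0, "dens": 0.1},
                {"datetime": "2018-04-01 23:00", "height": 300.0, "u": 2.0, "v": 0.0, "dens": 10.0},
            ]
        )
        df["wp"] = [-2.0, 4.0]
        exp = experienced_vs_available(df)
        assert exp.experienced_wp.mean > exp.available_wp.mean
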