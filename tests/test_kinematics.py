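"""Speed derivation: SS_H filters, SS_T hypotenuse, diel labels,
transit speeds, summaries and correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_positions
from sharkspeed import kinematics as kin
from sharkspeed import synthetic
from sharkspeed.geodesy import local_degrees_per_meter
from sharkspeed.telemetry import POSITION_COLUMNS, SharkRecord

DLAT_1M, _ = local_degrees_per_meter(34.39)


def two_fix_track(dist_m, dt_s, depth=(np.nan, np.nan), tag="sim-00"):
    t0 = pd.Timestamp("2020-06-01T00:00:00Z")
    df = make_positions(
        [(34.39, -119.52, t0), (34.39 + dist_m * DLAT_1M, -119.52, t0 + pd.Timedelta(seconds=dt_s))],
        tag=tag,
    )
    df["depth"] = list(depth)
    return df


class TestComputeSsH:
    def test_distance_over_time(self, shark):
        sp = kin.compute_ss_h(two_fix_track(100.0, 100.0), shark)
        assert sp["ss_h"].iloc[0] == pytest.approx(1.0, rel=1e-5)
        assert sp["u_tl"].iloc[0] == pytest.approx(0.5, rel=1e-5)

    def test_gap_filter_boundary(self, shark):
        kept = kin.compute_ss_h(two_fix_track(100.0, 300.0), shark)
        dropped = kin.compute_ss_h(two_fix_track(100.0, 301.0), shark)
        assert len(kept) == 1
        assert len(dropped) == 0
        assert dropped.attrs["n_gap_removed"] == 1

    def test_speed_floor_exclusive_below(self, shark):
        dropped = kin.compute_ss_h(two_fix_track(9.0, 100.0), shark)  # 0.09 m/s
        kept = kin.compute_ss_h(two_fix_track(10.0, 100.0), shark)    # 0.10 m/s
        assert len(dropped) == 0
        assert dropped.attrs["n_floor_removed"] == 1
        assert len(kept) == 1

    def test_filter_order_gap_before_floor(self, shark):
        """A slow pair over a long gap is booked against the gap filter."""
        sp = kin.compute_ss_h(two_fix_track(9.0, 400.0), shark)  # 0.0225 m/s over 400 s
        assert sp.attrs["n_gap_removed"] == 1
        assert sp.attrs["n_floor_removed"] == 0

    def test_zero_elapsed_dropped_counted(self, shark):
        df = two_fix_track(100.0, 100.0)
        df = pd.concat([df, df.iloc[[1]].assign(lat=34.4)], ignore_index=True)
        sp = kin.compute_ss_h(df, shark)
        assert sp.attrs["n_zero_elapsed"] == 1

    def test_unknown_shark_raises(self, shark):
        df = two_fix_track(100.0, 100.0, tag="someone-else")
        with pytest.raises(ValueError, match="expected only"):
            kin.compute_ss_h(df, shark)

    def test_scale_consistency(self, shark):
        """Doubling separations at fixed times doubles SS_H."""
        a = kin.compute_ss_h(two_fix_track(80.0, 200.0), shark)["ss_h"].iloc[0]
        b = kin.compute_ss_h(two_fix_track(160.0, 200.0), shark)["ss_h"].iloc[0]
        assert b == pytest.approx(2.0 * a, rel=1e-6)


class TestComputeSsT:
    def test_flat_pair_equal(self, shark):
        sp = kin.compute_ss_t(kin.compute_ss_h(two_fix_track(100.0, 100.0, depth=(5.0, 5.0)), shark))
        assert sp["ss_t"].iloc[0] == pytest.approx(sp["ss_h"].iloc[0])

    def test_three_four_five_triangle(self, shark):
        sp = kin.compute_ss_t(kin.compute_ss_h(two_fix_track(3.0, 1.0, depth=(1.0, 5.0)), shark))
        assert sp["ss_t"].iloc[0] == pytest.approx(5.0 / 1.0, rel=1e-4)
        assert sp["ss_h"].iloc[0] == pytest.approx(3.0, rel=1e-4)

    def test_missing_depth_leaves_ss_t_empty(self, shark):
        sp = kin.compute_ss_t(kin.compute_ss_h(two_fix_track(100.0, 100.0, depth=(np.nan, 5.0)), shark))
        assert np.isnan(sp["ss_t"].iloc[0])

    def test_hypotenuse_inequality_on_synthetic(self):
        cfg = synthetic.TrackSimConfig(n_sharks=2, duration_days=0.5, seed=11)
        sharks = synthetic.default_sharks(2, with_depth_every=1)
        pos = synthetic.simulate_tracks(cfg, sharks)
        sp = kin.compute_ss_t(kin.compute_speeds(pos[POSITION_COLUMNS], sharks))
        ok = sp["ss_t"].notna()
        assert ok.any()
        assert (sp.loc[ok, "ss_t"] >= sp.loc[ok, "ss_h"] - 1e-12).all()


class TestDiel:
    def test_local_solar_noon_is_day(self):
        # ~12:00 solar time at 119.52 W is ~19:58 UTC
        assert kin.classify_diel("2020-06-15T19:58:00Z", 34.39, -119.52)[0] == "day"

    def test_local_solar_midnight_is_night(self):
        assert kin.classify_diel("2020-06-15T07:58:00Z", 34.39, -119.52)[0] == "night"

    def test_sunrise_boundary_inclusive(self):
        """First minute with non-negative elevation is labelled day."""
        times = pd.date_range("2020-06-15T12:00:00Z", "2020-06-15T14:00:00Z", freq="1min")
        from sharkspeed.solar import solar_elevation
        elev = solar_elevation(times, 34.39, -119.52)
        labels = kin.classify_diel(times, 34.39, -119.52)
        crossing = np.flatnonzero((elev[:-1] < 0) & (elev[1:] >= 0))
        assert crossing.size == 1
        assert labels[crossing[0]] == "night"
        assert labels[crossing[0] + 1] == "day"

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            kin.classify_diel("2020-06-15T12:00:00Z", 75.0, 0.0)


class TestTransit:
    @staticmethod
    def _frames(elapsed_hours, dist_m=28_780.0):
        t0 = pd.Timestamp("2020-06-01T00:00:00Z")
        dep = pd.DataFrame({
            "shark_id": [f"s{i}" for i in range(len(elapsed_hours))],
            "timestamp": t0,
            "lat": 34.39, "lon": -119.52,
        })
        arr = dep.copy()
        arr["timestamp"] = [t0 + pd.Timedelta(hours=h) for h in elapsed_hours]
        arr["lat"] = dep["lat"] + dist_m * DLAT_1M
        return dep, arr

    def test_speed_arithmetic(self):
        dep, arr = self._frames([8.0])
        out = kin.transit_speeds(dep, arr, exclude_above_median_time=False)
        assert out["ss_transit"].iloc[0] == pytest.approx(28_780.0 / (8 * 3600), rel=1e-4)

    def test_median_time_exclusion_with_ties(self):
        # 12 animals; even-count median = mean of central pair = 6 h;
        # exactly 3 elapsed times exceed it -> 9 included
        dep, arr = self._frames([1, 2, 3, 4, 5, 6, 6, 6, 6, 10, 11, 12])
        out = kin.transit_speeds(dep, arr)
        assert out["included"].sum() == 9
        assert out.attrs["n_included"] == 9

    def test_exclusion_off_includes_all(self):
        dep, arr = self._frames([1, 5, 20])
        out = kin.transit_speeds(dep, arr, exclude_above_median_time=False)
        assert out["included"].all()

    def test_unmatched_shark_skipped_with_warning(self):
        dep, arr = self._frames([8.0, 9.0])
        with pytest.warns(UserWarning, match="unmatched"):
            out = kin.transit_speeds(dep, arr.iloc[[0]])
        assert list(out["shark_id"]) == ["s0"]


class TestSummaries:
    def test_single_estimate_flagged(self):
        df = pd.DataFrame({"shark_id": ["a"], "ss_h": [0.6]})
        out = kin.summarize_speeds(df)
        assert out.loc[0, "median"] == 0.6
        assert out.loc[0, "se"] == 0.0
        assert out.loc[0, "n"] == 1

    def test_median_of_skewed_triple(self):
        df = pd.DataFrame({"shark_id": "a", "ss_h": [0.1, 0.6, 7.7]})
        assert kin.summarize_speeds(df).loc[0, "median"] == 0.6

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kin.summarize_speeds(pd.DataFrame({"shark_id": [], "ss_h": []}))


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert kin.correlate(x, 3 * x + 1) == pytest.approx(1.0)
        assert kin.correlate(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            kin.correlate(np.ones(10), np.arange(10.0))

    def test_recovers_simulated_correlation(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.3 * x + np.sqrt(1 - 0.3**2) * rng.normal(size=n)
        assert kin.correlate(x, y) == pytest.approx(0.3, abs=0.05)
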