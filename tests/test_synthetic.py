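"""Generator behaviour: determinism, degenerate regimes, configured
distributions, and ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from sharkspeed import kinematics, synthetic, telemetry
from sharkspeed.telemetry import POSITION_COLUMNS


class TestTrackGenerator:
    def test_seeded_determinism(self):
        cfg = synthetic.TrackSimConfig(n_sharks=2, duration_days=0.2, seed=1)
        sharks = synthetic.default_sharks(2)
        a = synthetic.simulate_tracks(cfg, sharks)
        b = synthetic.simulate_tracks(cfg, sharks)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        sharks = synthetic.default_sharks(1)
        a = synthetic.simulate_tracks(
            synthetic.TrackSimConfig(n_sharks=1, duration_days=0.2, seed=1), sharks)
        b = synthetic.simulate_tracks(
            synthetic.TrackSimConfig(n_sharks=1, duration_days=0.2, seed=2), sharks)
        assert not a["lat"].equals(b["lat"])

    def test_degenerate_walk_exact_speed(self, shark):
        """No jitter, zero log-sd, constant interval: every derived SS_H
        equals the configured median."""
        cfg = synthetic.TrackSimConfig(
            n_sharks=1, duration_days=0.05, speed_log_sd=0.0, hpe_mean_m=0.0,
            rest_prob=0.0, day_night_speed_ratio=1.0, constant_interval=True, seed=4,
        )
        pos = synthetic.simulate_tracks(cfg, [shark])
        sp = kinematics.compute_ss_h(pos[POSITION_COLUMNS], shark)
        assert sp["ss_h"].to_numpy() == pytest.approx(
            np.full(len(sp), cfg.speed_median_ms), rel=1e-3
        )

    def test_ground_truth_speed_matches_noise_free_pipeline(self, shark):
        cfg = synthetic.TrackSimConfig(
            n_sharks=1, duration_days=0.1, hpe_mean_m=0.0, rest_prob=0.0, seed=5,
        )
        pos = synthetic.simulate_tracks(cfg, [shark])
        sp = kinematics.compute_ss_h(pos[POSITION_COLUMNS], shark,
                                     max_gap_s=np.inf, min_speed_ms=0.0)
        truth = pos["true_speed_ms"].iloc[1:].to_numpy()
        assert sp["ss_h"].to_numpy() == pytest.approx(truth, rel=1e-3)

    def test_hpe_exceedance_fraction(self):
        cfg = synthetic.TrackSimConfig(n_sharks=1, duration_days=14.0, seed=6)
        pos = synthetic.simulate_tracks(cfg, synthetic.default_sharks(1))
        frac = (pos["hpe"] > 5.0).mean()
        n = len(pos)
        tol = 3 * np.sqrt(cfg.frac_hpe_gt5 * (1 - cfg.frac_hpe_gt5) / n)
        assert frac == pytest.approx(cfg.frac_hpe_gt5, abs=tol)

    def test_hpe_mean(self):
        cfg = synthetic.TrackSimConfig(n_sharks=1, duration_days=14.0, seed=7)
        pos = synthetic.simulate_tracks(cfg, synthetic.default_sharks(1))
        assert pos["hpe"].mean() == pytest.approx(cfg.hpe_mean_m, rel=0.05)

    def test_sub_floor_speeds_generated(self):
        cfg = synthetic.TrackSimConfig(n_sharks=1, duration_days=7.0, seed=8)
        pos = synthetic.simulate_tracks(cfg, synthetic.default_sharks(1))
        assert (pos["true_speed_ms"].dropna() < 0.1).mean() > 0.005

    def test_some_gaps_exceed_filter(self):
        cfg = synthetic.TrackSimConfig(n_sharks=1, duration_days=2.0, seed=9)
        pos = synthetic.simulate_tracks(cfg, synthetic.default_sharks(1))
        gaps = pos["timestamp"].diff().dt.total_seconds().dropna()
        assert (gaps > 300.0).any()

    def test_depth_only_for_sensor_tags(self):
        cfg = synthetic.TrackSimConfig(n_sharks=2, duration_days=0.1, seed=10)
        sharks = synthetic.default_sharks(2, with_depth_every=2)
        pos = synthetic.simulate_tracks(cfg, sharks)
        with_depth = pos.loc[pos["tag_id"] == sharks[0].shark_id, "depth"]
        without = pos.loc[pos["tag_id"] == sharks[1].shark_id, "depth"]
        assert with_depth.notna().all()
        assert without.isna().all()
        lo, hi = cfg.depth_range_m
        assert with_depth.between(lo, hi).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(synthetic.InvalidConfigError):
            synthetic.TrackSimConfig(duration_days=-1.0)
        with pytest.raises(synthetic.InvalidConfigError):
            synthetic.TrackSimConfig(fix_interval_mean_s=0.0)
        with pytest.raises(synthetic.InvalidConfigError):
            synthetic.TrackSimConfig(frac_hpe_gt5=1.5)
        with pytest.raises(synthetic.InvalidConfigError):
            synthetic.simulate_tracks(synthetic.TrackSimConfig(), [])

    def test_unreachable_hpe_mixture_rejected(self):
        cfg = synthetic.TrackSimConfig(hpe_mean_m=1.0, frac_hpe_gt5=0.4,
                                       n_sharks=1, duration_days=0.05)
        with pytest.raises(synthetic.InvalidConfigError, match="unreachable"):
            synthetic.simulate_tracks(cfg, synthetic.default_sharks(1))

    def test_output_is_readable_by_io_module(self, tmp_path):
        cfg = synthetic.TrackSimConfig(n_sharks=1, duration_days=0.05, seed=11)
        pos = synthetic.simulate_tracks(cfg, synthetic.default_sharks(1))
        path = tmp_path / "sim.csv"
        telemetry.write_positions(pos[POSITION_COLUMNS], path)
        back = telemetry.read_positions(path)
        assert len(back) == len(pos)


class TestTemperatureGenerator:
    def test_constant_regime_exact(self):
        cfg = synthetic.TempFieldSimConfig(
            n_obs=100, noise_sd_C=0.0, depth_max_m=0.0, diel_amplitude_C=0.0, seed=1
        )
        obs = synthetic.simulate_temperature_obs(cfg)
        assert (obs["temp_C"] == cfg.surface_mean_C).all()

    def test_linear_stratification(self):
        cfg = synthetic.TempFieldSimConfig(stratification_C_per_m=0.5, diel_amplitude_C=0.0)
        assert cfg.true_field(10.0, 0.0) == pytest.approx(cfg.surface_mean_C - 5.0)

    def test_empirical_range_within_bounds(self):
        cfg = synthetic.TempFieldSimConfig(n_obs=50_000, seed=2)
        obs = synthetic.simulate_temperature_obs(cfg)
        lo = cfg.surface_mean_C - cfg.stratification_C_per_m * cfg.depth_max_m \
            - cfg.diel_amplitude_C - 5 * cfg.noise_sd_C
        hi = cfg.surface_mean_C + cfg.diel_amplitude_C + 5 * cfg.noise_sd_C
        assert obs["temp_C"].between(lo, hi).all()
        assert obs["depth_m"].between(0, cfg.depth_max_m).all()
        assert obs["time_of_day_min"].between(0, 1440).all()

    def test_determinism(self):
        cfg = synthetic.TempFieldSimConfig(n_obs=500, seed=3)
        pd.testing.assert_frame_equal(
            synthetic.simulate_temperature_obs(cfg), synthetic.simulate_temperature_obs(cfg)
        )


class TestUavGenerator:
    def test_pixel_displacement_arithmetic(self):
        track = synthetic.simulate_uav_track(0.6, 60.0, 2.0, 10, 0.0278)
        d = np.hypot(np.diff(track["px_x"]), np.diff(track["px_y"]))
        assert d == pytest.approx(np.full(9, 0.6 * 2.0 / 0.0278))
        assert d[0] == pytest.approx(43.17, abs=0.01)

    def test_zero_speed_stationary(self):
        track = synthetic.simulate_uav_track(0.0, 60.0, 2.0, 10, 0.0278)
        assert track["px_x"].nunique() == 1
        assert track["px_y"].nunique() == 1

    def test_invalid_args(self):
        with pytest.raises(synthetic.InvalidConfigError):
            synthetic.simulate_uav_track(0.6, 0.0, 2.0, 10, 0.0278)


class TestAr1:
    def test_marginal_moments_and_autocorrelation(self):
        x = synthetic.ar1_series(100_000, 0.7, sd=2.0, rng=1, mean=5.0)
        assert x.mean() == pytest.approx(5.0, abs=0.1)
        assert x.std() == pytest.approx(2.0, rel=0.05)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.7, abs=0.02)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError):
            synthetic.ar1_series(100, 1.0)
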