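"""Synthetic telemetry, temperature and UAV fixtures.

No raw telemetry ships with this package, so every downstream stage is
exercised on generated data carrying the statistical structure the
analysis assumes: correlated-random-walk tracks with log-normally
distributed cruise speeds (median ~0.6 m/s, strong right skew), a
day/night multiplicative speed contrast, exponential inter-fix gaps
(so some pairs exceed the 300 s filter), occasional sub-0.1 m/s
"resting wobble" (so the speed floor is exercised), per-fix HPE draws
straddling the 5 m cutoff with Gaussian positional jitter of standard
deviation HPE/2 per axis, depth-stratified water temperature with diel
structure, and straight-line UAV pixel tracks.  Every generator keeps
its ground truth alongside the observables so recovery tests can
compare pipeline output against what was simulated.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geodesy import local_degrees_per_meter
from .solar import solar_elevation
from .telemetry import POSITION_COLUMNS, SharkRecord

DEFAULT_START = "2020-06-01T00:00:00Z"
DEFAULT_CENTER = (34.39, -119.52)  # nursery array off Carpinteria, CA


class InvalidConfigError(ValueError):
    """Generator configuration violates an invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidConfigError(msg)


@dataclass(frozen=True)
class TrackSimConfig:
    """Study conditions for the track generator.

    Defaults emulate the telemetry regime of the nursery-array study:
    opportunistic fixes (exponential gaps, mean 120 s), log-normal
    cruise speeds with median 0.6 m/s and log-sd 0.5, a modest diel
    speed contrast (day/night ratio 1.08, matching a ~0.64 vs 0.59 m/s
    day/night split), HPE averaging 3 m with 10% of fixes above the
    5 m cutoff, and a 3% resting state below the 0.1 m/s floor.
    """

    n_sharks: int = 3
    duration_days: float = 2.0
    fix_interval_mean_s: float = 120.0
    speed_median_ms: float = 0.6
    speed_log_sd: float = 0.5
    turn_concentration: float = 4.0
    hpe_mean_m: float = 3.0
    frac_hpe_gt5: float = 0.10
    depth_range_m: tuple[float, float] = (0.0, 20.0)
    day_night_speed_ratio: float = 1.08
    rest_prob: float = 0.03
    rest_max_ms: float = 0.12
    constant_interval: bool = False
    center: tuple[float, float] = DEFAULT_CENTER
    start: str = DEFAULT_START
    seed: int = 0

    def __post_init__(self):
        _require(self.n_sharks >= 1, "n_sharks must be >= 1")
        _require(self.duration_days > 0, "duration_days must be positive")
        _require(self.fix_interval_mean_s > 0, "fix_interval_mean_s must be positive")
        _require(self.speed_median_ms > 0, "speed_median_ms must be positive")
        _require(self.speed_log_sd >= 0, "speed_log_sd must be non-negative")
        _require(self.turn_concentration > 0, "turn_concentration must be positive")
        _require(self.hpe_mean_m >= 0, "hpe_mean_m must be non-negative")
        _require(0.0 <= self.frac_hpe_gt5 <= 1.0, "frac_hpe_gt5 must be in [0, 1]")
        _require(self.depth_range_m[1] >= self.depth_range_m[0] >= 0,
                 "depth_range_m must satisfy 0 <= min <= max")
        _require(self.day_night_speed_ratio > 0, "day_night_speed_ratio must be positive")
        _require(0.0 <= self.rest_prob < 1.0, "rest_prob must be in [0, 1)")


def _lognormal_hpe_params(mean_m: float, frac_gt: float, cutoff: float = 5.0):
    """(mu, sigma) of a log-normal with given mean and P(X > cutoff).

    Solved numerically; raises InvalidConfigError when no log-normal
    can have that combination (the exceedance probability of a
    fixed-mean log-normal below the cutoff is bounded above).
    """
    if frac_gt <= 0.0:
        if mean_m > cutoff:
            raise InvalidConfigError("frac_hpe_gt5 = 0 impossible with mean above cutoff")
        return np.log(mean_m), 1e-9

    def exceed(sigma):
        mu = np.log(mean_m) - sigma**2 / 2.0
        return stats.norm.sf((np.log(cutoff) - mu) / sigma)

    if mean_m < cutoff:
        sigma_star = np.sqrt(2.0 * np.log(cutoff / mean_m))
        max_frac = exceed(sigma_star)
        if frac_gt > max_frac:
            raise InvalidConfigError(
                f"frac_hpe_gt5={frac_gt} unreachable with hpe_mean_m={mean_m} "
                f"(max {max_frac:.3f})"
            )
        hi = sigma_star
    else:
        hi = 20.0
        if frac_gt >= exceed(1e-9):
            raise InvalidConfigError("frac_hpe_gt5 too large for hpe mean above cutoff")
    sigma = optimize.brentq(lambda s: exceed(s) - frac_gt, 1e-9, hi, xtol=1e-12)
    return np.log(mean_m) - sigma**2 / 2.0, sigma


def _simulate_one_track(config: TrackSimConfig, shark: SharkRecord, rng) -> pd.DataFrame:
    if config.constant_interval:
        n = int(round(config.duration_days * 86400.0 / config.fix_interval_mean_s))
        gaps = np.full(max(n, 2), config.fix_interval_mean_s)
    else:
        n = int(round(config.duration_days * 86400.0 / config.fix_interval_mean_s))
        gaps = rng.exponential(config.fix_interval_mean_s, size=max(n, 2))
        gaps = np.maximum(gaps, 1.0)  # positioning cannot resolve sub-second refixes
    t0 = pd.Timestamp(config.start)
    times = t0 + pd.to_timedelta(np.concatenate([[0.0], np.cumsum(gaps)]), unit="s")
    n_fix = len(times)

    # per-segment cruise speed: log-normal around the median, diel factor,
    # occasional resting wobble below the floor
    if config.speed_log_sd > 0:
        speeds = rng.lognormal(np.log(config.speed_median_ms), config.speed_log_sd, n_fix - 1)
    else:
        speeds = np.full(n_fix - 1, config.speed_median_ms)
    r = config.day_night_speed_ratio
    if r != 1.0:
        elev = solar_elevation(times[:-1], config.center[0], config.center[1])
        speeds = speeds * np.where(elev >= 0.0, np.sqrt(r), 1.0 / np.sqrt(r))
    if config.rest_prob > 0:
        resting = rng.random(n_fix - 1) < config.rest_prob
        speeds = np.where(resting, rng.uniform(0.0, config.rest_max_ms, n_fix - 1), speeds)

    # correlated random walk: persistent heading with von Mises turns
    theta = np.cumsum(
        np.concatenate([[rng.uniform(0, 2 * np.pi)],
                        rng.vonmises(0.0, config.turn_concentration, n_fix - 2)])
    ) if n_fix > 2 else np.array([rng.uniform(0, 2 * np.pi)])
    step = speeds * gaps
    x = np.concatenate([[0.0], np.cumsum(step * np.cos(theta))])
    y = np.concatenate([[0.0], np.cumsum(step * np.sin(theta))])

    dlat_per_m, dlon_per_m = local_degrees_per_meter(config.center[0])
    true_lat = config.center[0] + y * dlat_per_m
    true_lon = config.center[1] + x * dlon_per_m

    if config.hpe_mean_m > 0:
        mu, sigma = _lognormal_hpe_params(config.hpe_mean_m, config.frac_hpe_gt5)
        hpe = rng.lognormal(mu, sigma, n_fix)
        jitter_sd = hpe / 2.0  # HPE is an error scale; mapping documented, configurable via hpe_mean_m
        lat = true_lat + rng.normal(0.0, 1.0, n_fix) * jitter_sd * dlat_per_m
        lon = true_lon + rng.normal(0.0, 1.0, n_fix) * jitter_sd * dlon_per_m
    else:
        hpe = np.zeros(n_fix)
        lat, lon = true_lat, true_lon

    d0, d1 = config.depth_range_m
    if shark.has_depth_sensor and d1 > d0:
        # bounded random walk in depth, reflected at the range limits
        steps = rng.normal(0.0, 0.15 * (d1 - d0), n_fix)
        raw = d0 + (d1 - d0) / 2.0 + np.cumsum(steps)
        period = 2.0 * (d1 - d0)
        depth = d0 + np.abs((raw - d0) % period - (d1 - d0))
    elif shark.has_depth_sensor:
        depth = np.full(n_fix, d0)
    else:
        depth = np.full(n_fix, np.nan)

    return pd.DataFrame({
        "tag_id": shark.shark_id,
        "timestamp": times,
        "lat": lat,
        "lon": lon,
        "hpe": hpe,
        "depth": depth,
        "true_lat": true_lat,
        "true_lon": true_lon,
        "true_speed_ms": np.concatenate([[np.nan], speeds]),
    })


def simulate_tracks(config: TrackSimConfig, sharks: list[SharkRecord]) -> pd.DataFrame:
    """Correlated-random-walk telemetry for a list of animals.

    Returns the canonical position table (tag_id, timestamp, lat, lon,
    hpe, depth) plus ground-truth columns ``true_lat``/``true_lon``
    (jitter-free positions) and ``true_speed_ms`` (the simulated speed
    of the segment ending at each fix; NaN on the first fix).
    Byte-identical output under identical config and sharks.
    """
    if not sharks:
        raise InvalidConfigError("need at least one shark")
    pieces = []
    for i, shark in enumerate(sharks):
        rng = np.random.default_rng([config.seed, i])
        pieces.append(_simulate_one_track(config, shark, rng))
    out = pd.concat(pieces, ignore_index=True)
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"], tz="UTC")
    return out


@dataclass(frozen=True)
class TempFieldSimConfig:
    """Study conditions for the temperature-field generator.

    The noiseless field is surface_mean - stratification * depth plus a
    diel sinusoid peaking mid-afternoon (15:00); defaults span roughly
    12-22 deg C over a 40 m water column, the range observed over a
    stratified nearshore array.
    """

    n_obs: int = 5000
    lat_lon_bounds: tuple[float, float, float, float] = (34.37, 34.41, -119.55, -119.49)
    depth_max_m: float = 40.0
    surface_mean_C: float = 20.0
    stratification_C_per_m: float = 0.2
    diel_amplitude_C: float = 1.0
    noise_sd_C: float = 0.1
    seed: int = 0

    def __post_init__(self):
        _require(self.n_obs >= 1, "n_obs must be >= 1")
        _require(self.depth_max_m >= 0, "depth_max_m must be non-negative")
        _require(self.noise_sd_C >= 0, "noise_sd_C must be non-negative")
        lat0, lat1, lon0, lon1 = self.lat_lon_bounds
        _require(lat1 >= lat0 and lon1 >= lon0, "lat_lon_bounds must be ordered")

    def true_field(self, depth_m, time_of_day_min) -> np.ndarray:
        """Noiseless field value; the ground truth for MAE evaluation."""
        depth_m = np.asarray(depth_m, dtype=float)
        tod = np.asarray(time_of_day_min, dtype=float)
        diel = self.diel_amplitude_C * np.sin(2.0 * np.pi * (tod - 540.0) / 1440.0)
        return self.surface_mean_C - self.stratification_C_per_m * depth_m + diel


def simulate_temperature_obs(config: TempFieldSimConfig) -> pd.DataFrame:
    """Temperature observations drawn from the configured field + noise.

    Columns match the interpolator's feature schema (lat, lon, depth_m,
    day_of_year, time_of_day_min, temp_C) plus ``temp_true_C``.
    """
    rng = np.random.default_rng(config.seed)
    lat0, lat1, lon0, lon1 = config.lat_lon_bounds
    n = config.n_obs
    depth = rng.uniform(0.0, config.depth_max_m, n) if config.depth_max_m > 0 else np.zeros(n)
    tod = rng.uniform(0.0, 1440.0, n)
    df = pd.DataFrame({
        "lat": rng.uniform(lat0, lat1, n),
        "lon": rng.uniform(lon0, lon1, n),
        "depth_m": depth,
        "day_of_year": rng.integers(130, 350, n).astype(float),  # May-December season
        "time_of_day_min": tod,
    })
    truth = config.true_field(depth, tod)
    noise = rng.normal(0.0, config.noise_sd_C, n) if config.noise_sd_C > 0 else 0.0
    df["temp_true_C"] = truth
    df["temp_C"] = truth + noise
    return df


def simulate_uav_track(
    speed_ms: float,
    altitude_m: float,
    frame_interval_s: float,
    n_frames: int,
    gsd_m: float,
    heading_deg: float = 30.0,
    start_px: tuple[float, float] = (500.0, 500.0),
) -> pd.DataFrame:
    """Straight-line pixel track of a shark crossing the UAV arena.

    Pixel displacement per step is speed_ms * frame_interval_s / gsd_m,
    split between x and y by the heading.  ``speed_ms`` may be 0 (a
    stationary animal); all other arguments must be positive.
    """
    if speed_ms < 0:
        raise InvalidConfigError("speed_ms must be non-negative")
    for name, v in [("altitude_m", altitude_m), ("frame_interval_s", frame_interval_s),
                    ("n_frames", n_frames), ("gsd_m", gsd_m)]:
        if v <= 0:
            raise InvalidConfigError(f"{name} must be positive")
    t = np.arange(n_frames, dtype=float) * frame_interval_s
    step_px = speed_ms * frame_interval_s / gsd_m
    h = np.radians(heading_deg)
    return pd.DataFrame({
        "time_s": t,
        "px_x": start_px[0] + np.arange(n_frames) * step_px * np.cos(h),
        "px_y": start_px[1] + np.arange(n_frames) * step_px * np.sin(h),
    })


def ar1_series(n: int, phi: float, sd: float = 1.0, rng=None, mean: float = 0.0) -> np.ndarray:
    """Stationary AR(1) series: x_t = mean + phi*(x_{t-1}-mean) + eps.

    Innovation sd is scaled so the marginal sd equals ``sd``.  Used by
    the bootstrap calibration simulations as a null with known serial
    correlation.
    """
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must be in (-1, 1) for stationarity")
    rng = np.random.default_rng(rng)
    from scipy.signal import lfilter

    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    x = lfilter([1.0], [1.0, -phi], eps)
    return mean + x


def default_sharks(n: int, with_depth_every: int = 2) -> list[SharkRecord]:
    """Convenience cohort of synthetic animals spanning the study size range."""
    tls = np.linspace(152, 315, n)
    sexes = ["F", "M", "U"]
    return [
        SharkRecord(
            shark_id=f"sim-{i:02d}",
            tl_cm=float(tl),
            fl_cm=float(0.9 * tl),
            mass_kg=float(3.57e-6 * (0.9 * tl) ** 3.25),
            sex=sexes[i % 3],
            has_depth_sensor=(i % with_depth_every == 0),
        )
        for i, tl in enumerate(tls)
    ]
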