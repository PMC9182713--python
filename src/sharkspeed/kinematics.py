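"""Swim-speed derivation from filtered positions.

Horizontal swim speed (SS_H) is speed over ground: the WGS84 geodesic
distance between successive fixes of one animal divided by the elapsed
time.  True swim speed (SS_T) additionally accounts for the depth
change between the fixes, assuming a constant dive angle, so it is the
hypotenuse speed sqrt(dist_h^2 + ddepth^2) / dt and can never be less
than SS_H.  Candidate pairs pass two filters, applied in this fixed
order: pairs with elapsed time > 300 s are removed (positions that far
apart say little about instantaneous speed), then estimates below the
0.1 m/s floor are removed (sub-floor values are dominated by position
error while the animal mills about).  Speeds standardised to body
length (U = SS_H / TL) make animals of different sizes comparable.

Transit speeds between two receiver arrays use the same
distance-over-time construction at whole-journey scale.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import vincenty_distance
from .solar import classify_diel as _classify_diel
from .telemetry import SharkRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP_S = 300.0
DEFAULT_MIN_SPEED_MS = 0.1

SPEED_COLUMNS = [
    "shark_id", "t_start", "t_end", "elapsed_s", "dist_h_m",
    "lat_mid", "lon_mid", "depth_start_m", "depth_end_m",
    "delta_depth_m", "depth_mid_m", "ss_h", "ss_t", "u_tl",
    "temp_C", "diel",
]


def geodesic_distance(lat1, lon1, lat2, lon2):
    """Geodesic (Vincenty) distance in metres on WGS84; see :mod:`.geodesy`."""
    return vincenty_distance(lat1, lon1, lat2, lon2)


def compute_ss_h(
    positions: pd.DataFrame,
    shark: SharkRecord,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_speed_ms: float = DEFAULT_MIN_SPEED_MS,
) -> pd.DataFrame:
    """Horizontal swim speeds for one animal's sorted, HPE-filtered fixes.

    One candidate per consecutive fix pair.  Zero-elapsed pairs are
    dropped and counted; the gap filter (elapsed > ``max_gap_s``
    removed) runs before the speed floor (ss_h < ``min_speed_ms``
    removed) — the floor is exclusive, exactly ``min_speed_ms`` is
    retained.  ``u_tl`` is filled from the shark's total length.

    Filter bookkeeping lands in ``.attrs``: ``n_candidates``,
    ``n_zero_elapsed``, ``n_gap_removed``, ``n_floor_removed``.
    """
    tags = positions["tag_id"].unique()
    if len(tags) and not (len(tags) == 1 and str(tags[0]) == shark.shark_id):
        raise ValueError(
            f"positions contain tag(s) {list(tags)}, expected only {shark.shark_id!r}"
        )
    ts = pd.DatetimeIndex(positions["timestamp"])
    if ts.size and (np.diff(ts.asi8) < 0).any():
        raise ValueError("positions must be sorted by timestamp")

    n = len(positions)
    out = pd.DataFrame(columns=SPEED_COLUMNS)
    counts = {"n_candidates": max(n - 1, 0), "n_zero_elapsed": 0,
              "n_gap_removed": 0, "n_floor_removed": 0}
    if n < 2:
        out.attrs.update(counts)
        return out

    lat = positions["lat"].to_numpy(float)
    lon = positions["lon"].to_numpy(float)
    depth = positions["depth"].to_numpy(float) if "depth" in positions else np.full(n, np.nan)
    elapsed = np.diff(ts.asi8) / 1e9

    dist = vincenty_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])

    nonzero = elapsed > 0
    counts["n_zero_elapsed"] = int((~nonzero).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        ss_h = np.where(nonzero, dist / np.where(nonzero, elapsed, 1.0), np.nan)

    df = pd.DataFrame({
        "shark_id": shark.shark_id,
        "t_start": ts[:-1],
        "t_end": ts[1:],
        "elapsed_s": elapsed,
        "dist_h_m": dist,
        "lat_mid": 0.5 * (lat[:-1] + lat[1:]),
        "lon_mid": 0.5 * (lon[:-1] + lon[1:]),
        "depth_start_m": depth[:-1],
        "depth_end_m": depth[1:],
        "ss_h": ss_h,
    })
    df = df[nonzero]

    gap_ok = df["elapsed_s"] <= max_gap_s
    counts["n_gap_removed"] = int((~gap_ok).sum())
    df = df[gap_ok]

    floor_ok = df["ss_h"] >= min_speed_ms
    counts["n_floor_removed"] = int((~floor_ok).sum())
    df = df[floor_ok].reset_index(drop=True)

    df["delta_depth_m"] = (df["depth_end_m"] - df["depth_start_m"]).abs()
    df["depth_mid_m"] = 0.5 * (df["depth_start_m"] + df["depth_end_m"])
    df["ss_t"] = np.nan
    df["u_tl"] = df["ss_h"] / (shark.tl_cm / 100.0)
    df["temp_C"] = np.nan
    df["diel"] = pd.NA
    df = df[SPEED_COLUMNS]
    df.attrs.update(counts)
    logger.info(
        "%s: %d candidate pair(s) -> %d speed estimate(s) "
        "(%d zero-elapsed, %d gap-filtered, %d below floor)",
        shark.shark_id, counts["n_candidates"], len(df),
        counts["n_zero_elapsed"], counts["n_gap_removed"], counts["n_floor_removed"],
    )
    return df


def compute_speeds(
    positions: pd.DataFrame,
    sharks: list[SharkRecord],
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_speed_ms: float = DEFAULT_MIN_SPEED_MS,
) -> pd.DataFrame:
    """Concatenated :func:`compute_ss_h` over every tagged animal."""
    by_id = {s.shark_id: s for s in sharks}
    unknown = set(positions["tag_id"].unique()) - set(by_id)
    if unknown:
        raise ValueError(f"positions reference unknown shark id(s): {sorted(unknown)}")
    pieces, attrs = [], {}
    for tag, grp in positions.groupby("tag_id", sort=False):
        piece = compute_ss_h(grp, by_id[tag], max_gap_s=max_gap_s, min_speed_ms=min_speed_ms)
        for k, v in piece.attrs.items():
            attrs[k] = attrs.get(k, 0) + v
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(columns=SPEED_COLUMNS)
    out.attrs.update(attrs)
    return out


def compute_ss_t(speeds: pd.DataFrame) -> pd.DataFrame:
    """Fill true swim speed where both endpoint depths are known.

    ss_t = sqrt(dist_h^2 + delta_depth^2) / elapsed — the hypotenuse of
    a constant-angle dive between the fixes.  Pairs missing a depth
    keep ss_t empty (NaN); that is not an error.
    """
    out = speeds.copy()
    has_depth = out["depth_start_m"].notna() & out["depth_end_m"].notna()
    dd = (out.loc[has_depth, "depth_end_m"] - out.loc[has_depth, "depth_start_m"]).abs()
    out.loc[has_depth, "delta_depth_m"] = dd
    out.loc[has_depth, "ss_t"] = (
        np.hypot(out.loc[has_depth, "dist_h_m"], dd) / out.loc[has_depth, "elapsed_s"]
    )
    out.attrs.update(speeds.attrs)
    return out


def classify_diel(timestamps, site_lat: float, site_lon: float) -> np.ndarray:
    """Day/night labels at the array site; day iff sun elevation >= 0."""
    return _classify_diel(timestamps, site_lat, site_lon)


def add_diel(speeds: pd.DataFrame, site_lat: float, site_lon: float) -> pd.DataFrame:
    """Label each estimate day/night at the pair midpoint time."""
    out = speeds.copy()
    if not len(out):
        return out
    t_mid = pd.DatetimeIndex(out["t_start"]) + (
        pd.DatetimeIndex(out["t_end"]) - pd.DatetimeIndex(out["t_start"])
    ) / 2
    out["diel"] = _classify_diel(t_mid, site_lat, site_lon)
    out.attrs.update(speeds.attrs)
    return out


def transit_speeds(
    departures: pd.DataFrame,
    arrivals: pd.DataFrame,
    exclude_above_median_time: bool = True,
) -> pd.DataFrame:
    """Per-animal transit speed between two receiver arrays.

    ``departures`` holds each animal's last fix at the origin array and
    ``arrivals`` its first detection at the destination (columns
    shark_id/tag_id, timestamp, lat, lon).  Speed is the geodesic
    distance over the elapsed time.  With the median-time exclusion on,
    animals whose elapsed time is strictly greater than the cohort
    median (even count: mean of the central pair) get
    ``included=False``; the returned frame's ``.attrs`` carry the mean
    and SD of ss_transit over included animals.
    """
    def _index(df):
        key = "shark_id" if "shark_id" in df.columns else "tag_id"
        return df.set_index(df[key].astype(str))

    dep, arr = _index(departures), _index(arrivals)
    common = [i for i in dep.index if i in arr.index]
    skipped = sorted(set(dep.index).symmetric_difference(arr.index))
    if skipped:
        warnings.warn(f"unmatched shark(s) skipped in transit calculation: {skipped}")
    rows = []
    for sid in common:
        d, a = dep.loc[sid], arr.loc[sid]
        elapsed = (pd.Timestamp(a["timestamp"]) - pd.Timestamp(d["timestamp"])).total_seconds()
        if elapsed <= 0:
            warnings.warn(f"non-positive transit time for {sid}; skipped")
            continue
        dist = vincenty_distance(d["lat"], d["lon"], a["lat"], a["lon"])
        rows.append({"shark_id": sid, "dist_m": dist, "elapsed_s": elapsed,
                     "ss_transit": dist / elapsed})
    out = pd.DataFrame(rows, columns=["shark_id", "dist_m", "elapsed_s", "ss_transit"])
    if not len(out):
        out["included"] = pd.Series(dtype=bool)
        return out
    if exclude_above_median_time:
        med = float(np.median(out["elapsed_s"]))
        out["included"] = out["elapsed_s"] <= med
    else:
        out["included"] = True
    inc = out.loc[out["included"], "ss_transit"]
    out.attrs["mean_ss_transit"] = float(inc.mean())
    out.attrs["sd_ss_transit"] = float(inc.std(ddof=1)) if len(inc) > 1 else 0.0
    out.attrs["n_included"] = int(out["included"].sum())
    return out


def summarize_speeds(
    speeds: pd.DataFrame,
    group_keys: list[str] | None = None,
    value: str = "ss_h",
) -> pd.DataFrame:
    """Median, mean, standard error and n of a speed column per group.

    The median is the headline statistic (speed distributions are
    strongly right-skewed); SE = sd / sqrt(n), reported as 0.0 for
    singleton groups (flagged by n = 1).  Empty groups are omitted
    with a warning.
    """
    if not len(speeds):
        raise ValueError("no speed estimates to summarise")
    group_keys = group_keys or ["shark_id"]
    rows = []
    for key, grp in speeds.groupby(group_keys, sort=True, dropna=True, observed=True):
        vals = grp[value].dropna().to_numpy(float)
        if not len(vals):
            warnings.warn(f"group {key!r} has no {value} values; omitted")
            continue
        key = key if isinstance(key, tuple) else (key,)
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(dict(zip(group_keys, key)) | {
            "n": len(vals),
            "median": float(np.median(vals)),
            "mean": float(np.mean(vals)),
            "se": se,
        })
    return pd.DataFrame(rows)


def correlate(x, y) -> float:
    """Pearson product-moment correlation of paired values.

    Only r is returned — no p-value: serial autocorrelation in
    telemetry-derived series makes the usual significance machinery
    misleading, so correlations are descriptive here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
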