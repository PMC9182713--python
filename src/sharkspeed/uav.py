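"""UAV pixel-track photogrammetry: ground sampling distance, swim
speeds and body sizes from nadir drone video.

A hovering drone with a downward-pointing camera turns the sea surface
into a measuring arena: a pixel at altitude h corresponds to a ground
length gsd = sensor_dim * h / (focal_length * image_dim) metres, so
frame-to-frame pixel displacements divided by the frame interval give
speed over ground, and pixel body lengths give total length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CameraSpec:
    """Physical camera constants needed for ground-sampling distance."""

    focal_length_mm: float
    sensor_width_mm: float
    sensor_height_mm: float
    image_width_px: int
    image_height_px: int

    def __post_init__(self):
        for name in (
            "focal_length_mm", "sensor_width_mm", "sensor_height_mm",
            "image_width_px", "image_height_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class TrackTooShortError(ValueError):
    """Track rejected: present in the arena for less than the minimum duration."""


def gsd(camera: CameraSpec, altitude_m: float, axis: str = "height") -> float:
    """Ground sampling distance in metres per pixel along one image axis.

    gsd = (sensor dimension [mm] * altitude [m]) / (focal length [mm] *
    image dimension [px]).  ``axis`` selects which sensor/image pair is
    used; 'height' is the default because the study camera's vertical
    axis (8.8 mm over 2160 px) is the calibrated one.
    """
    if altitude_m <= 0:
        raise ValueError("altitude_m must be positive")
    if axis == "width":
        sensor_mm, image_px = camera.sensor_width_mm, camera.image_width_px
    elif axis == "height":
        sensor_mm, image_px = camera.sensor_height_mm, camera.image_height_px
    else:
        raise ValueError("axis must be 'width' or 'height'")
    return sensor_mm * altitude_m / (camera.focal_length_mm * image_px)


def track_speeds(
    track: pd.DataFrame,
    gsd_m: float,
    min_duration_s: float = 60.0,
    tl_m: float | None = None,
) -> pd.DataFrame:
    """Per-step swim speeds from a pixel track.

    ``track`` needs columns ``time_s``, ``px_x``, ``px_y`` with strictly
    increasing times.  Each step speed is the Euclidean pixel
    displacement times ``gsd_m`` over the step interval.  Tracks whose
    total duration is below ``min_duration_s`` (exclusive: exactly the
    minimum is accepted) raise :class:`TrackTooShortError`.  When
    ``tl_m`` is given a ``u_tl`` column (total lengths per second) is
    added.

    Returns a DataFrame of per-step ``speed_ms`` (and ``u_tl``) with
    ``median_speed_ms``/``median_u_tl`` stored in ``.attrs``.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 frames")
    if gsd_m <= 0:
        raise ValueError("gsd_m must be positive")
    t = np.asarray(track["time_s"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("track times must be strictly increasing")
    duration = t[-1] - t[0]
    if duration < min_duration_s:
        raise TrackTooShortError(
            f"track duration {duration:.1f} s < minimum {min_duration_s:.0f} s"
        )
    dx = np.diff(np.asarray(track["px_x"], dtype=float))
    dy = np.diff(np.asarray(track["px_y"], dtype=float))
    dt = np.diff(t)
    speed = np.hypot(dx, dy) * gsd_m / dt
    out = pd.DataFrame({
        "t_start_s": t[:-1],
        "t_end_s": t[1:],
        "speed_ms": speed,
    })
    out.attrs["median_speed_ms"] = float(np.median(speed))
    if tl_m is not None:
        if tl_m <= 0:
            raise ValueError("tl_m must be positive")
        out["u_tl"] = speed / tl_m
        out.attrs["median_u_tl"] = float(np.median(out["u_tl"]))
    return out


def batch_track_speeds(
    tracks: dict[str, pd.DataFrame],
    gsd_m: float,
    min_duration_s: float = 60.0,
    sizes_tl_m: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Median speeds per observation, skipping too-short tracks with a warning."""
    rows = []
    for obs_id, tr in tracks.items():
        tl = None if sizes_tl_m is None else sizes_tl_m.get(obs_id)
        try:
            steps = track_speeds(tr, gsd_m, min_duration_s=min_duration_s, tl_m=tl)
        except TrackTooShortError as exc:
            warnings.warn(f"observation {obs_id} rejected: {exc}")
            continue
        rows.append({
            "obs_id": obs_id,
            "n_steps": len(steps),
            "median_speed_ms": steps.attrs["median_speed_ms"],
            "median_u_tl": steps.attrs.get("median_u_tl", np.nan),
        })
    return pd.DataFrame(rows)


def size_from_pixels(length_px: float, gsd_m: float) -> float:
    """Body length in metres from a pixel measurement; 0 px is flagged invalid."""
    if gsd_m <= 0:
        raise ValueError("gsd_m must be positive")
    if length_px < 0:
        raise ValueError("length_px must be non-negative")
    if length_px == 0:
        warnings.warn("zero-pixel length measurement is invalid; returning 0")
    return length_px * gsd_m
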