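"""Inverse geodesic distances on the WGS84 ellipsoid.

Speed-over-ground estimation divides the geodesic (Vincenty) distance
between successive trilaterated positions by the elapsed time, so the
distance primitive must be accurate at the tens-of-metres scale typical
of fine-scale acoustic positioning, yet cheap enough to evaluate for
tens of thousands of consecutive-fix pairs at once.  The implementation
below is the classical Vincenty inverse iteration, vectorised over
numpy arrays.  Vincenty's iteration can fail to converge for nearly
antipodal points; those (irrelevant at telemetry scales) fall back to a
great-circle distance on a sphere of mean radius and are reported via a
module logger.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

# WGS84 ellipsoid
WGS84_A = 6378137.0            # semi-major axis, m
WGS84_F = 1.0 / 298.257223563  # flattening
WGS84_B = WGS84_A * (1.0 - WGS84_F)

_MEAN_RADIUS = (2.0 * WGS84_A + WGS84_B) / 3.0

_MAX_ITER = 200
_CONV_TOL = 1e-12


def _validate_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")


def _haversine(lat1, lon1, lat2, lon2):
    """Great-circle fallback on a mean-radius sphere (antipodal rescue)."""
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * _MEAN_RADIUS * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def vincenty_distance(lat1, lon1, lat2, lon2):
    """Vincenty inverse distance between points on WGS84, in metres.

    Parameters are decimal degrees; scalars or broadcastable arrays.
    Returns a float for scalar input, else an ndarray.  Symmetric and
    non-negative; identical points give exactly 0.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    )
    scalar = lat1.ndim == 0
    lat1, lon1, lat2, lon2 = (np.atleast_1d(x) for x in (lat1, lon1, lat2, lon2))
    _validate_coords(lat1, lon1)
    _validate_coords(lat2, lon2)

    phi1, lam1, phi2, lam2 = (np.radians(x) for x in (lat1, lon1, lat2, lon2))

    U1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    L = lam2 - lam1
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    coincident = (phi1 == phi2) & (lam1 == lam2)
    active = ~coincident
    converged = np.zeros_like(lam, dtype=bool)

    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(_MAX_ITER):
        if not np.any(active):
            break
        sin_lam, cos_lam = np.sin(lam[active]), np.cos(lam[active])
        cu1, su1 = cosU1[active], sinU1[active]
        cu2, su2 = cosU2[active], sinU2[active]

        t1 = cu2 * sin_lam
        t2 = cu1 * su2 - su1 * cu2 * cos_lam
        ss = np.sqrt(t1 ** 2 + t2 ** 2)
        cs = su1 * su2 + cu1 * cu2 * cos_lam
        sig = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss > 0, cu1 * cu2 * sin_lam / ss, 0.0)
        c2a = 1.0 - sin_alpha ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(c2a > 0, cs - 2.0 * su1 * su2 / np.where(c2a > 0, c2a, 1.0), 0.0)
        C = WGS84_F / 16.0 * c2a * (4.0 + WGS84_F * (4.0 - 3.0 * c2a))
        lam_new = L[active] + (1.0 - C) * WGS84_F * sin_alpha * (
            sig + C * ss * (c2sm + C * cs * (-1.0 + 2.0 * c2sm ** 2))
        )

        done = np.abs(lam_new - lam[active]) < _CONV_TOL

        sin_sigma[active] = ss
        cos_sigma[active] = cs
        sigma[active] = sig
        cos_sq_alpha[active] = c2a
        cos2sm[active] = c2sm
        lam[active] = lam_new

        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active = active & ~converged

    failed = active
    u_sq = cos_sq_alpha * (WGS84_A ** 2 - WGS84_B ** 2) / WGS84_B ** 2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    Bc = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = Bc * sin_sigma * (
        cos2sm
        + Bc / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm ** 2)
            - Bc / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma ** 2) * (-3.0 + 4.0 * cos2sm ** 2)
        )
    )
    dist = WGS84_B * A * (sigma - delta_sigma)
    dist[coincident] = 0.0

    if np.any(failed):
        logger.warning(
            "Vincenty iteration failed to converge for %d nearly antipodal pair(s); "
            "falling back to great-circle distance", int(failed.sum())
        )
        dist[failed] = _haversine(phi1[failed], lam1[failed], phi2[failed], lam2[failed])

    return float(dist[0]) if scalar else dist


def local_degrees_per_meter(lat_deg: float) -> tuple[float, float]:
    """(dlat, dlon) in degrees corresponding to 1 m north / 1 m east.

    First-order WGS84 radii of curvature at ``lat_deg``; used by the
    synthetic-track generator so that metre-scale walks laid onto the
    ellipsoid reproduce their step lengths under the inverse geodesic.
    """
    phi = np.radians(lat_deg)
    e2 = WGS84_F * (2.0 - WGS84_F)
    s2 = np.sin(phi) ** 2
    M = WGS84_A * (1.0 - e2) / (1.0 - e2 * s2) ** 1.5       # meridional radius
    N = WGS84_A / np.sqrt(1.0 - e2 * s2)                    # prime vertical
    return float(np.degrees(1.0 / M)), float(np.degrees(1.0 / (N * np.cos(phi))))
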