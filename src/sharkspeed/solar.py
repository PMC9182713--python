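"""Solar elevation and day/night classification.

Diel contrasts in cruising speed require labelling every speed estimate
as day or night.  The boundary used throughout is geometric sunrise and
sunset: a timestamp is "day" iff the sun's elevation at the reference
site is >= 0 degrees.  Elevation comes from the standard NOAA solar
position equations (fractional year, equation of time, declination),
accurate to a few hundredths of a degree — far finer than the minutes-
scale precision the diel label needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_ABS_LATITUDE = 66.0  # polar day/night not supported


def solar_elevation(timestamps, lat: float, lon: float) -> np.ndarray:
    """Sun elevation angle in degrees at UTC ``timestamps`` for a site.

    ``timestamps`` may be a single datetime, a DatetimeIndex or any
    sequence pandas can coerce; naive datetimes are taken as UTC.
    """
    if abs(lat) > MAX_ABS_LATITUDE:
        raise ValueError(
            f"latitude {lat} outside supported band (+/-{MAX_ABS_LATITUDE} deg): "
            "polar day/night is out of scope"
        )
    ts = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(timestamps, dtype=object)), utc=True))

    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy(dtype=float)
    minute = ts.minute.to_numpy(dtype=float)
    second = ts.second.to_numpy(dtype=float) + ts.microsecond.to_numpy(dtype=float) / 1e6
    frac_hour = hour + minute / 60.0 + second / 3600.0

    # fractional year (radians); leap-year day counts matter < 0.1 deg here
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (frac_hour - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )  # minutes
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )  # radians

    time_offset = eqtime + 4.0 * lon  # minutes (UTC input -> timezone term 0)
    tst = frac_hour * 60.0 + time_offset
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle

    phi = np.radians(lat)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    elevation = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return elevation


def classify_diel(timestamps, site_lat: float, site_lon: float) -> np.ndarray:
    """Label UTC timestamps 'day' or 'night' at a reference site.

    Day is defined inclusively: sun elevation >= 0 (sunrise and sunset
    instants are day).  Returns an object array of 'day'/'night';
    scalar input yields a length-1 array.
    """
    elev = solar_elevation(timestamps, site_lat, site_lon)
    return np.where(elev >= 0.0, "day", "night").astype(object)
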