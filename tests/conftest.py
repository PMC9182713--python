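import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sharkspeed.telemetry import SharkRecord  # noqa: E402


@pytest.fixture
def shark():
    return SharkRecord("sim-00", tl_cm=200.0, fl_cm=180.0, mass_kg=76.0,
                       sex="F", has_depth_sensor=True)


@pytest.fixture
def small_positions():
    """Three well-formed fixes for one tag, deliberately shuffled."""
    return pd.DataFrame({
        "tag_id": ["A", "A", "A"],
        "timestamp": pd.to_datetime(
            ["2020-06-01T00:02:00Z", "2020-06-01T00:00:00Z", "2020-06-01T00:01:00Z"]
        ),
        "lat": [34.391, 34.389, 34.390],
        "lon": [-119.520, -119.520, -119.520],
        "hpe": [2.0, 3.0, 4.0],
        "depth": [5.0, 4.0, 4.5],
    })


def make_positions(lat_lon_times, tag="A", hpe=1.0):
    """Canonical positions table from (lat, lon, iso_time) triples."""
    lats, lons, times = zip(*lat_lon_times)
    return pd.DataFrame({
        "tag_id": tag,
        "timestamp": pd.to_datetime(list(times), utc=True),
        "lat": list(lats),
        "lon": list(lons),
        "hpe": hpe,
        "depth": np.nan,
    })
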