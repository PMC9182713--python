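"""Bundled reference tables from the juvenile white shark study.

These are the printed per-animal inputs the worked examples and the
reproduction script run on: the morphometrics and median cruise speeds
of the 17 acoustically tracked juvenile white sharks retained for
analysis (an 18th animal, tracked for only 5 relocations, was excluded
at source), the 25 UAV-observed sharks, and the quadcopter camera
constants.  Camera numbers are manufacturer specifications for the
Phantom 4 Pro V2 (1-inch 13.2 x 8.8 mm sensor, 8.8 mm focal length,
4K video frame), not measured quantities.
"""

from __future__ import annotations

import pandas as pd

from .uav import CameraSpec

#: Array centre used as the diel-classification site (Carpinteria, CA nursery).
ARRAY_CENTER = (34.39, -119.52)

_COHORT_ROWS = [
    # shark_id, tl_cm, fl_cm, mass_kg, days_tracked, n_relocations,
    # median_ss_h_ms, se_ss_h, median_ss_t_ms, se_ss_t
    ("2020-13", 152, 138.0, 32.1, 64, 3943, 0.62, 0.004, None, None),
    ("2020-15", 217, 196.0, 100.3, 110, 5285, 0.62, 0.003, None, None),
    ("2020-16", 315, 283.5, 332.8, 113, 5508, 0.71, 0.004, None, None),
    ("2020-17", 259, 233.1, 176.2, 99, 6200, 0.66, 0.003, None, None),
    ("2020-19", 259, 233.1, 176.2, 107, 7802, 0.58, 0.003, 0.58, 0.003),
    ("2020-20", 155, 139.5, 33.2, 107, 14106, 0.58, 0.002, 0.58, 0.002),
    ("2020-21", 155, 139.5, 33.2, 107, 11256, 0.62, 0.002, 0.62, 0.002),
    ("2020-22", 183, 164.7, 57.0, 102, 4167, 0.59, 0.003, None, None),
    ("2020-31", 243, 218.7, 143.2, 35, 728, 0.71, 0.007, 0.71, 0.007),
    ("2020-32", 270, 243.0, 201.7, 49, 7854, 0.64, 0.004, 0.64, 0.004),
    ("2020-33", 183, 164.7, 57.0, 36, 3475, 0.56, 0.008, 0.56, 0.008),
    ("2020-34", 239, 215.1, 135.7, 17, 1325, 0.68, 0.005, None, None),
    ("2020-35", 183, 164.7, 57.0, 2, 118, 0.61, 0.018, None, None),
    ("2020-36", 183, 164.7, 57.0, 36, 3161, 0.56, 0.005, None, None),
    ("2020-40", 244, 219.6, 145.1, 8, 326, 0.62, 0.012, None, None),
    ("2020-41", 198, 178.2, 73.6, 2, 102, 0.60, 0.023, None, None),
    ("2020-42", 200, 180.0, 76.0, 1, 34, 0.68, 0.042, None, None),
]

_UAV_ROWS = [
    # obs_id, tl_cm, n_observations, median_u_tl (TL/s)
    (1, 290, 29, 0.29), (2, 215, 41, 0.33), (3, 244, 62, 0.31),
    (4, 234, 44, 0.27), (5, 242, 39, 0.29), (6, 221, 83, 0.24),
    (7, 235, 47, 0.29), (8, 240, 48, 0.27), (9, 216, 57, 0.27),
    (10, 219, 74, 0.30), (11, 242, 43, 0.26), (12, 230, 57, 0.27),
    (13, 260, 44, 0.31), (14, 224, 48, 0.31), (15, 260, 48, 0.29),
    (16, 209, 51, 0.25), (17, 209, 46, 0.37), (18, 260, 43, 0.24),
    (19, 247, 39, 0.29), (20, 187, 39, 0.38), (21, 191, 62, 0.26),
    (22, 251, 45, 0.24), (23, 237, 50, 0.26), (24, 182, 51, 0.27),
    (25, 230, 42, 0.29),
]

#: Default UAV camera: Phantom 4 Pro V2 shooting 4K video.
PHANTOM_4_PRO = CameraSpec(
    focal_length_mm=8.8,
    sensor_width_mm=13.2,
    sensor_height_mm=8.8,
    image_width_px=3840,
    image_height_px=2160,
)


def study_cohort() -> pd.DataFrame:
    """Per-shark morphometrics and median cruise speeds (17 animals)."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "shark_id", "tl_cm", "fl_cm", "mass_kg", "days_tracked",
            "n_relocations", "median_ss_h_ms", "se_ss_h",
            "median_ss_t_ms", "se_ss_t",
        ],
    ).astype({"median_ss_t_ms": float, "se_ss_t": float})


def uav_observations() -> pd.DataFrame:
    """UAV-observed sharks: size and median length-standardised speed."""
    return pd.DataFrame(
        _UAV_ROWS, columns=["obs_id", "tl_cm", "n_observations", "median_u_tl"]
    )
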