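"""Morphometric conversions and metabolic-rate estimators.

Two estimators of routine oxygen consumption are provided.

Speed regression (mass-specific field routine metabolic rate, fRMR):

    MO2 = SMR * 10**(slope * U)

with U the cruising speed in total lengths per second, SMR = 246
mg O2 kg^-1 h^-1 the empirical standard metabolic rate of captive
young-of-the-year white sharks (the U = 0 intercept), and slope 0.58
from the mako-shark swimming performance curve.  All logs are base 10.

Allometric whole-body routine metabolic rate:

    RMR = a * M**b        [mg O2 h^-1]

with M body mass in kg, b = 0.79 the lamnid allometric scaling
exponent, and a the antilog of the lamnid-curve intercept.  No default
is shipped for a — it is a literature value that must be supplied (or
back-solved from a published whole-body rate); asking for it silently
would hide a load-bearing assumption.

Length conversions: fork length is a fixed fraction of total length
(0.9, recovered from the study cohort's printed TL/FL pairs), and mass
follows a power law in fork length with coefficients fitted by
least-squares in log10 space to the cohort's (FL, mass) pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_SLOPE = 0.58
DEFAULT_SMR = 246.0          # mg O2 kg^-1 h^-1 at U = 0
DEFAULT_SCALING_EXPONENT = 0.79
DEFAULT_TL_TO_FL = 0.9
SENSITIVITY_SLOPES = (0.58, 0.79, 0.97)


def fl_from_tl(tl_cm, factor: float = DEFAULT_TL_TO_FL):
    """Fork length from total length (cm); default factor 0.9."""
    tl_cm = np.asarray(tl_cm, dtype=float)
    if np.any(tl_cm <= 0):
        raise ValueError("total length must be positive")
    out = factor * tl_cm
    return float(out) if out.ndim == 0 else out


def fit_tl_fl_factor(tl_cm, fl_cm) -> float:
    """Least-squares through-origin factor FL = f * TL from paired lengths."""
    tl = np.asarray(tl_cm, dtype=float)
    fl = np.asarray(fl_cm, dtype=float)
    if np.any(tl <= 0) or np.any(fl <= 0):
        raise ValueError("lengths must be positive")
    return float(np.sum(tl * fl) / np.sum(tl * tl))


def fit_length_mass(fl_cm, mass_kg) -> tuple[float, float]:
    """Fit mass = a * FL**b by least squares in log10 space.

    Returns (a, b).  On the study cohort this gives a ~ 3.57e-6,
    b ~ 3.25 — the usual near-cubic fish length-weight relation.
    """
    fl = np.asarray(fl_cm, dtype=float)
    m = np.asarray(mass_kg, dtype=float)
    if np.any(fl <= 0) or np.any(m <= 0):
        raise ValueError("lengths and masses must be positive")
    if len(fl) < 2:
        raise ValueError("need at least 2 pairs to fit")
    b, log_a = np.polyfit(np.log10(fl), np.log10(m), 1)
    return float(10.0 ** log_a), float(b)


def mass_from_fl(fl_cm, lw_coeff_a: float, lw_exp_b: float):
    """Power-law body mass (kg) from fork length (cm)."""
    fl_cm = np.asarray(fl_cm, dtype=float)
    if np.any(fl_cm <= 0) or lw_coeff_a <= 0:
        raise ValueError("fork length and coefficient must be positive")
    out = lw_coeff_a * fl_cm ** lw_exp_b
    return float(out) if out.ndim == 0 else out


def frmr_from_speed(u_tl, slope: float = DEFAULT_SLOPE, smr: float = DEFAULT_SMR):
    """Mass-specific fRMR (mg O2 kg^-1 h^-1) from cruising speed U (TL/s).

    MO2 = smr * 10**(slope * u_tl); strictly increasing in U, equal to
    the standard metabolic rate at U = 0.
    """
    u = np.asarray(u_tl, dtype=float)
    if np.any(u < 0):
        raise ValueError("u_tl must be non-negative")
    if smr <= 0:
        raise ValueError("smr must be positive")
    out = smr * 10.0 ** (slope * u)
    return float(out) if out.ndim == 0 else out


def speed_from_frmr(mo2, slope: float = DEFAULT_SLOPE, smr: float = DEFAULT_SMR):
    """Inverse of :func:`frmr_from_speed`: U = log10(MO2/smr) / slope."""
    mo2 = np.asarray(mo2, dtype=float)
    if np.any(mo2 <= 0):
        raise ValueError("mo2 must be positive")
    out = np.log10(mo2 / smr) / slope
    return float(out) if out.ndim == 0 else out


def whole_body_rmr(mass_kg, a: float | None = None, b: float = DEFAULT_SCALING_EXPONENT):
    """Whole-body routine metabolic rate a * M**b (mg O2 h^-1).

    ``a`` has no default: the lamnid-curve intercept is not bundled
    and must be supplied explicitly (see module docstring).
    """
    if a is None:
        raise ValueError(
            "scaling coefficient 'a' (antilog of the lamnid-curve intercept) "
            "must be supplied; there is no safe default"
        )
    mass = np.asarray(mass_kg, dtype=float)
    if np.any(mass <= 0) or a <= 0:
        raise ValueError("mass and coefficient must be positive")
    out = a * mass ** b
    return float(out) if out.ndim == 0 else out


def coefficient_sensitivity(
    u_tl_grid,
    slopes: tuple[float, ...] = SENSITIVITY_SLOPES,
    smr: float = DEFAULT_SMR,
) -> pd.DataFrame:
    """fRMR surface over a speed grid for several regression slopes.

    Long-format table (u_tl, slope, mo2); shares the SMR intercept at
    U = 0 and is monotone increasing in both slope and U.
    """
    u = np.asarray(u_tl_grid, dtype=float)
    if u.size == 0:
        raise ValueError("u_tl_grid must be non-empty")
    rows = []
    for s in slopes:
        rows.append(pd.DataFrame({
            "u_tl": u, "slope": s, "mo2": frmr_from_speed(u, slope=s, smr=smr),
        }))
    return pd.concat(rows, ignore_index=True)


def cohort_frmr(
    summaries: pd.DataFrame,
    slope: float = DEFAULT_SLOPE,
    smr: float = DEFAULT_SMR,
) -> tuple[pd.DataFrame, dict]:
    """Per-animal fRMR from median cruise speeds, plus cohort statistics.

    ``summaries`` needs shark_id, tl_cm and either median_u_tl or
    median_ss_h_ms (converted via TL).  Animals missing a total length
    are skipped with a warning.  Returns (per-shark table, summary
    dict with min/max/mean/sd/n of the mass-specific estimates).
    """
    rows = []
    for row in summaries.itertuples(index=False):
        tl = getattr(row, "tl_cm", None)
        if tl is None or not np.isfinite(tl):
            warnings.warn(f"shark {row.shark_id} missing total length; skipped")
            continue
        if hasattr(row, "median_u_tl") and np.isfinite(getattr(row, "median_u_tl")):
            u = float(row.median_u_tl)
        else:
            u = float(row.median_ss_h_ms) / (float(tl) / 100.0)
        rows.append({
            "shark_id": row.shark_id,
            "tl_cm": float(tl),
            "median_u_tl": u,
            "mo2_mass_specific": frmr_from_speed(u, slope=slope, smr=smr),
            "method": "speed_regression",
            "slope_coeff": slope,
            "smr_intercept": smr,
        })
    if not rows:
        raise ValueError("no shark with both a median speed and a total length")
    table = pd.DataFrame(rows)
    vals = table["mo2_mass_specific"].to_numpy()
    summary = {
        "n": int(len(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }
    return table, summary
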