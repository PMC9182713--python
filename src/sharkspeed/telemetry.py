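"""Reading, validation and filtering of positional telemetry.

The positioning system emits one trilaterated fix per detection burst:
tag id, UTC timestamp, latitude, longitude, a horizontal position
error estimate (HPE, metres) and, for pressure-sensing tags, depth.
This module maps vendor CSV exports onto the package's canonical
column set, enforces the ordering/uniqueness invariants downstream
kinematics rely on, and applies the HPE quality filter.  All row
counts removed by cleaning or filtering are logged and can be written
to a JSON provenance sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

POSITION_COLUMNS = ["tag_id", "timestamp", "lat", "lon", "hpe", "depth"]

#: Innovasea VPS-export-style headers mapped to canonical names.
DEFAULT_COLUMN_MAP = {
    "FullId": "tag_id",
    "Time": "timestamp",
    "Latitude": "lat",
    "Longitude": "lon",
    "HPE": "hpe",
    "Depth": "depth",
}


class SchemaError(ValueError):
    """Input file cannot be mapped onto the canonical position schema."""


@dataclass
class SchemaConfig:
    """How to read a positions file: column mapping and timezone.

    ``column_map`` maps file headers to canonical names; canonical
    headers already present pass through.  ``timezone`` declares the
    zone of naive input timestamps (internally everything is UTC).
    ``strict`` controls whether unparseable rows abort or are dropped
    with a counted warning.
    """

    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    timezone: str = "UTC"
    strict: bool = False

    @classmethod
    def from_yaml(cls, path) -> "SchemaConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            column_map=raw.get("column_map", dict(DEFAULT_COLUMN_MAP)),
            timezone=raw.get("timezone", "UTC"),
            strict=bool(raw.get("strict", False)),
        )


@dataclass(frozen=True)
class SharkRecord:
    """Per-animal morphometrics and tag capability."""

    shark_id: str
    tl_cm: float
    fl_cm: float
    mass_kg: float
    sex: str = "U"
    has_depth_sensor: bool = False

    def __post_init__(self):
        if not (self.tl_cm > self.fl_cm > 0):
            raise ValueError("require tl_cm > fl_cm > 0")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if self.sex not in {"F", "M", "U"}:
            raise ValueError("sex must be one of F, M, U")


def read_sharks(path) -> list[SharkRecord]:
    """Read shark metadata CSV (shark_id, tl_cm, fl_cm, mass_kg, sex, has_depth_sensor)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(SharkRecord(
            shark_id=str(row.shark_id),
            tl_cm=float(row.tl_cm),
            fl_cm=float(row.fl_cm),
            mass_kg=float(row.mass_kg),
            sex=getattr(row, "sex", "U"),
            has_depth_sensor=bool(getattr(row, "has_depth_sensor", False)),
        ))
    return records


def _validate_positions(df: pd.DataFrame) -> None:
    if df["lat"].abs().gt(90).any():
        raise ValueError("latitude outside [-90, 90]")
    if df["lon"].abs().gt(180).any():
        raise ValueError("longitude outside [-180, 180]")
    if df["hpe"].lt(0).any():
        raise ValueError("negative HPE")
    if "depth" in df and df["depth"].dropna().lt(0).any():
        raise ValueError("negative depth (convention: metres below surface, >= 0)")


def clean_positions(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (tag_id, timestamp) and drop duplicate fixes keeping the first."""
    n0 = len(df)
    df = df.sort_values(["tag_id", "timestamp"], kind="mergesort")
    df = df.drop_duplicates(subset=["tag_id", "timestamp"], keep="first")
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d duplicate (tag_id, timestamp) fix(es)", dropped)
    df = df.reset_index(drop=True)
    df.attrs["n_input"] = n0
    df.attrs["n_duplicates_dropped"] = dropped
    return df


def read_positions(path, schema: SchemaConfig | None = None) -> pd.DataFrame:
    """Read a delimited positions file into the canonical table.

    Output columns: tag_id (str), timestamp (tz-aware UTC), lat, lon,
    hpe, depth (NaN when absent); sorted by (tag_id, timestamp) with
    duplicate fixes dropped keeping the first occurrence.
    """
    schema = schema or SchemaConfig()
    df = pd.read_csv(path)
    rename = {src: dst for src, dst in schema.column_map.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in ("tag_id", "timestamp", "lat", "lon", "hpe") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s) {missing} after mapping")
    if "depth" not in df.columns:
        df["depth"] = np.nan

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        msg = f"{int(bad.sum())} row(s) with unparseable timestamps"
        if schema.strict:
            raise ValueError(msg)
        warnings.warn(msg + " dropped")
    if getattr(ts.dt, "tz", None) is None:
        ts = ts.dt.tz_localize(schema.timezone)
    ts = ts.dt.tz_convert("UTC")
    df = df.assign(timestamp=ts).loc[~ts.isna()].copy()
    df["tag_id"] = df["tag_id"].astype(str)
    for col in ("lat", "lon", "hpe", "depth"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    _validate_positions(df)
    out = clean_positions(df[POSITION_COLUMNS])
    out.attrs["n_unparseable_dropped"] = int(bad.sum())
    logger.info("read %d position(s) from %s", len(out), path)
    return out


def write_positions(df: pd.DataFrame, path) -> None:
    """Write the canonical position table as CSV (lossless round-trip)."""
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out[POSITION_COLUMNS].to_csv(path, index=False)


def filter_hpe(positions: pd.DataFrame, max_hpe: float = 5.0) -> pd.DataFrame:
    """Keep fixes whose horizontal position error is <= ``max_hpe`` metres.

    The cutoff is inclusive.  Retention counts are logged and stored in
    ``.attrs``; an empty result triggers a warning rather than an error.
    """
    kept = positions.loc[positions["hpe"] <= max_hpe].reset_index(drop=True)
    logger.info("HPE filter (<= %g m): kept %d of %d", max_hpe, len(kept), len(positions))
    if len(positions) and not len(kept):
        warnings.warn(f"HPE filter (<= {max_hpe} m) removed every fix")
    kept.attrs["n_before_hpe"] = len(positions)
    kept.attrs["n_after_hpe"] = len(kept)
    kept.attrs["max_hpe"] = max_hpe
    return kept


def count_speed_slots(positions: pd.DataFrame) -> int:
    """Number of consecutive-pair speed estimates available before filtering.

    Each tag with n fixes contributes n - 1 pairs: sum over tags of
    (n_fixes - 1).
    """
    if not len(positions):
        return 0
    counts = positions.groupby("tag_id", sort=False).size()
    return int((counts - 1).clip(lower=0).sum())


def write_provenance(path, **counts) -> None:
    """Write filter/cleaning counts to a JSON sidecar."""
    Path(path).write_text(json.dumps(counts, indent=2, default=int))
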