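"""Readers and writers for the pipeline's on-disk formats.

All tables are plain CSV with UTC ISO-8601 timestamps; geometry layers are
GeoJSON in WGS84 lon/lat. Readers are tolerant of extra columns (warn,
ignore) but fail loudly, naming the column, when a required one is missing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

#: Particle-count channels: particles larger than 0.3/0.5/1/2.5/5/10 um.
PNC_COLS = ["pnc_gt0p3", "pnc_gt0p5", "pnc_gt1", "pnc_gt2p5", "pnc_gt5", "pnc_gt10"]
#: Mass channels: PM1, PM2.5, PM10 in ug/m3.
MASS_COLS = ["pm1", "pm25", "pm10"]
POLLUTION_COLS = PNC_COLS + MASS_COLS

STREAM_COLS = ["participant_id", "timestamp_utc"] + POLLUTION_COLS + [
    "temp_c",
    "rh_pct",
    "lat",
    "lon",
]
STATION_COLS = ["station_id", "lat", "lon", "timestamp_utc", "pm25"]
LABEL_COLS = [
    "participant_id",
    "timestamp_utc",
    "microenv",
    "indoor",
    "segment_id",
    "segment_kind",
]


class SchemaError(ValueError):
    pass


def _check_schema(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what}: ignoring unknown column(s) {extra}", stacklevel=3)
    return df[required]


def _parse_times(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], utc=True, errors="coerce")
    return df


def read_stream(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": "string"})
    df = _check_schema(df, STREAM_COLS, f"personal stream {path}")
    return _parse_times(df)


def write_stream(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False, float_format="%.6f")


def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": "string"})
    df = _check_schema(df, STATION_COLS, f"station series {path}")
    return _parse_times(df)


def write_stations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False, float_format="%.6f")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": "string", "segment_kind": "string"})
    df = _check_schema(df, LABEL_COLS, f"context labels {path}")
    df = _parse_times(df)
    df["indoor"] = df["indoor"].astype(bool)
    return df


def write_labels(df: pd.DataFrame, path) -> None:
    out = df[LABEL_COLS].copy()
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, float_format="%.6g") -> None:
    df.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, seed: int, config_text: str, files: list[str]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "crs": "WGS84 lon/lat on disk; local azimuthal equidistant for metric math",
        "files": {f: file_sha256(outdir / f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
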