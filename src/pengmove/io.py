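"""Readers and writers for the study bundle: tracks CSV, dives CSV,
environment NetCDF, and the JSON manifest.

Timestamps are UTC ISO-8601 throughout. CSV is used for tabular data,
NetCDF for gridded fields, JSON for reports and model summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

ENV_VARIABLES = ("sst", "mld", "sic", "chla", "uo", "vo", "u10", "v10")

__all__ = [
    "ENV_VARIABLES",
    "StudyBundle",
    "read_tracks",
    "write_tracks",
    "read_dives",
    "write_dives",
    "read_env",
    "write_env",
    "write_bundle",
    "read_bundle",
]


def _read_table(path, time_col: str, required: tuple) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["id", time_col, *required])
    missing = [c for c in ("id", time_col, *required) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    try:
        df[time_col] = pd.to_datetime(df[time_col], utc=True).dt.tz_localize(None)
    except (ValueError, TypeError) as e:
        bad = pd.to_datetime(df[time_col], utc=True, errors="coerce")
        line = int(bad.isna().idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: unparseable {time_col} near line {line}: {e}") from None
    for c in required:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().sum() > df[c].isna().sum():
            line = int((vals.isna() & df[c].notna()).idxmax()) + 2
            raise ValueError(f"{path}: unparseable numeric value in '{c}' near line {line}")
        df[c] = vals
    df = df.sort_values(["id", time_col], kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["id", time_col])
    if dup.any():
        warnings.warn(f"{path}: {int(dup.sum())} duplicate timestamps collapsed to first")
        df = df[~dup].reset_index(drop=True)
    return df


def read_tracks(path) -> pd.DataFrame:
    """Read a track CSV (id, timestamp, lon, lat, extra columns preserved)."""
    df = _read_table(path, "timestamp", ("lon", "lat"))
    if len(df) and ((df["lat"].abs() > 90).any()):
        raise ValueError(f"{path}: latitude outside [-90, 90]")
    return df


def write_tracks(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.6f")


def read_dives(path) -> pd.DataFrame:
    """Read a dive-summary CSV (id, start, max_depth_m, duration_s, surface_s)."""
    return _read_table(path, "start", ("max_depth_m", "duration_s", "surface_s"))


def write_dives(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.4f")


def read_env(path, name_map: dict | None = None) -> xr.Dataset:
    """Open an environment NetCDF and validate dims/variables/coords.

    ``name_map`` maps file variable names to the canonical names
    (sst, mld, sic, chla, uo, vo, u10, v10). A descending latitude axis is
    normalized to ascending; non-monotone coordinates are an error.
    """
    ds = xr.open_dataset(path)
    if name_map:
        ds = ds.rename(name_map)
    for dim in ("lon", "lat", "time"):
        if dim not in ds.dims:
            raise ValueError(f"{path}: missing dimension '{dim}'")
    missing = [v for v in ENV_VARIABLES if v not in ds.data_vars]
    if missing:
        raise ValueError(f"{path}: missing variables {missing}")
    lat = ds["lat"].values
    if np.all(np.diff(lat) < 0):
        ds = ds.isel(lat=slice(None, None, -1))
        lat = ds["lat"].values
    for coord in ("lon", "lat"):
        if not np.all(np.diff(ds[coord].values) > 0):
            raise ValueError(f"{path}: non-monotone coordinate '{coord}'")
    if not np.all(np.diff(ds["time"].values.astype("int64")) > 0):
        raise ValueError(f"{path}: non-monotone time coordinate")
    return ds


def write_env(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path)


@dataclass
class StudyBundle:
    """Paths + manifest of one study dataset on disk."""

    tracks_path: Path
    dives_path: Path
    env_path: Path
    manifest: dict

    def load(self):
        tracks = read_tracks(self.tracks_path)
        dives = read_dives(self.dives_path)
        env = read_env(self.env_path)
        extra = set(dives["id"]) - set(tracks["id"])
        if extra:
            raise ValueError(f"dive individuals missing from tracks: {sorted(extra)}")
        return tracks, dives, env


def write_bundle(tracks, dives, env, manifest, outdir) -> StudyBundle:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = StudyBundle(
        tracks_path=outdir / "tracks.csv",
        dives_path=outdir / "dives.csv",
        env_path=outdir / "env.nc",
        manifest=manifest,
    )
    write_tracks(tracks, b.tracks_path)
    write_dives(dives, b.dives_path)
    write_env(env, b.env_path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return b


def read_bundle(indir) -> StudyBundle:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    if "seed" not in manifest:
        raise ValueError("manifest without a seed: not a synthetic study bundle")
    return StudyBundle(
        tracks_path=indir / "tracks.csv",
        dives_path=indir / "dives.csv",
        env_path=indir / "env.nc",
        manifest=manifest,
    )
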