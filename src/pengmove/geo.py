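"""Spherical geometry, projection and track time-series utilities.

All public functions work in degrees; radians are internal only. The Earth
is modelled as a sphere of radius 6371.0 km, matching the spherical
great-circle conventions of the R tracking packages this pipeline mirrors.
Longitudes are normalized to the half-open interval [-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "normalize_lon",
    "great_circle_km",
    "initial_bearing",
    "laea_project",
    "laea_inverse",
    "interpolate_regular",
    "angular_difference",
    "unwrap_lon",
]


def normalize_lon(lon):
    """Normalize longitude(s) to [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GeoPoint:
    """A location on the sphere: lon degrees east in [-180, 180), lat in [-90, 90]."""

    lon: float
    lat: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))


def _as_lonlat(p) -> tuple[float, float]:
    if isinstance(p, GeoPoint):
        return p.lon, p.lat
    lon, lat = p
    return float(normalize_lon(lon)), float(lat)


def great_circle_km(a, b) -> float:
    """Haversine great-circle distance in km on a sphere of radius 6371 km.

    Accepts GeoPoint or (lon, lat) pairs; also broadcasts over array inputs.
    """
    lon1, lat1 = _as_lonlat(a)
    lon2, lat2 = _as_lonlat(b)
    return float(haversine_km(lon1, lat1, lon2, lat2))


def haversine_km(lon1, lat1, lon2, lat2):
    """Vectorized haversine distance (km). Inputs in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards roundoff for antipodal points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


class UndefinedHeadingError(ValueError):
    """Raised when a bearing is requested between coincident points."""


def initial_bearing(a, b) -> float:
    """Forward azimuth at ``a`` toward ``b``, degrees clockwise from north in [0, 360).

    Raises UndefinedHeadingError for coincident points.
    """
    lon1, lat1 = _as_lonlat(a)
    lon2, lat2 = _as_lonlat(b)
    if lon1 == lon2 and lat1 == lat2:
        raise UndefinedHeadingError("bearing undefined for coincident points")
    return float(bearing_deg(lon1, lat1, lon2, lat2))


def bearing_deg(lon1, lat1, lon2, lat2):
    """Vectorized initial bearing (degrees in [0, 360)). Inputs in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


class ProjectionDomainError(ValueError):
    """Point cannot be projected (antipodal to the projection center)."""


def laea_project(p, center) -> tuple[float, float]:
    """Spherical Lambert azimuthal equal-area forward projection, km.

    Snyder's forward equations on the sphere; ``center`` maps to (0, 0).
    The antipode of the center is outside the projection domain.
    """
    lon, lat = _as_lonlat(p)
    lon0, lat0 = _as_lonlat(center)
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    if denom <= 1e-12:
        raise ProjectionDomainError("point is antipodal to the projection center")
    kp = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * kp * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * kp * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return float(x), float(y)


def laea_xy(lons, lats, center):
    """Vectorized spherical Lambert azimuthal equal-area forward projection (km)."""
    lon0, lat0 = _as_lonlat(center)
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    if np.any(denom <= 1e-12):
        raise ProjectionDomainError("point antipodal to the projection center")
    kp = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * kp * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * kp * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def laea_inverse(xy, center) -> tuple[float, float]:
    """Inverse of :func:`laea_project`; returns (lon, lat) in degrees."""
    x, y = xy
    lon0, lat0 = _as_lonlat(center)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    x, y = x / EARTH_RADIUS_KM, y / EARTH_RADIUS_KM
    rho = np.hypot(x, y)
    if rho < 1e-12:
        return float(normalize_lon(lon0)), float(lat0)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
    phi = np.arcsin(
        np.clip(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / rho, -1.0, 1.0)
    )
    lam = lam0 + np.arctan2(
        x * np.sin(c), rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)
    )
    return float(normalize_lon(np.degrees(lam))), float(np.degrees(phi))


def angular_difference(heading, flow_toward):
    """(heading - flow_toward) mod 360, in degrees within [0, 360).

    Both arguments are bearings in degrees clockwise from north; broadcasts.
    """
    return (np.asarray(heading, dtype=float) - np.asarray(flow_toward, dtype=float)) % 360.0


def unwrap_lon(lon_deg):
    """Unwrap a longitude sequence (degrees) so consecutive steps take the short way."""
    lon = np.asarray(lon_deg, dtype=float)
    return np.degrees(np.unwrap(np.radians(lon)))


def interpolate_regular(
    track: pd.DataFrame, step_hours: float = 12.0, max_gap_hours: float = 48.0
) -> pd.DataFrame:
    """Re-interpolate a fix series onto a regular time grid.

    ``track`` needs columns ``timestamp`` (datetime, strictly increasing),
    ``lon`` and ``lat``. Latitude and unwrapped longitude are interpolated
    linearly on a grid anchored at the first fix; output never extrapolates
    beyond the last fix, and no points are produced inside observation gaps
    longer than ``max_gap_hours`` (gap handling is this package's choice;
    satellite tags routinely fall silent for days).

    Longitudes are unwrapped before interpolation so crossings of the
    antimeridian or prime meridian interpolate along the short arc.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 fixes to interpolate")
    t = pd.to_datetime(track["timestamp"]).to_numpy()
    if not (np.diff(t.astype("int64")) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    t_sec = t.astype("datetime64[s]").astype("int64").astype(float)
    lon_u = unwrap_lon(track["lon"].to_numpy())
    lat = track["lat"].to_numpy(dtype=float)

    step = step_hours * 3600.0
    n_steps = int(np.floor((t_sec[-1] - t_sec[0]) / step))
    grid = t_sec[0] + step * np.arange(n_steps + 1)

    lon_i = np.interp(grid, t_sec, lon_u)
    lat_i = np.interp(grid, t_sec, lat)

    # mask grid points falling strictly inside an over-long observation gap
    gap_ok = np.ones(grid.shape, dtype=bool)
    idx = np.searchsorted(t_sec, grid, side="right") - 1
    idx = np.clip(idx, 0, len(t_sec) - 2)
    on_node = np.isin(grid, t_sec)
    gap_len = t_sec[idx + 1] - t_sec[idx]
    gap_ok = on_node | (gap_len <= max_gap_hours * 3600.0)

    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(grid[gap_ok].astype("int64"), unit="s"),
            "lon": normalize_lon(lon_i[gap_ok]),
            "lat": lat_i[gap_ok],
        }
    )
    if "id" in track.columns and len(track):
        out.insert(0, "id", track["id"].iloc[0])
    return out
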