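"""Synthetic study-bundle generator: Argos-like tracks, duty-cycled dive
records and gridded environmental fields.

The generator emulates the structure of a juvenile / non-breeding king
penguin tracking study from the Crozet Archipelago: birds leave the colony
(46.43°S, 51.86°E), encamp near the polar front in summer, transit
south-west, then range over a wide winter area before (some) returning.
Tags yield ~14.5 locations per day with Argos-like jitter and occasional
extreme outliers; dive summaries (~55 dives per recording day) are
transmitted on a 1-day-ON / 2-days-OFF duty cycle, with per-hour behavioral
regimes (traveling vs foraging) switching as a 2-state Markov chain.
Environmental fields (SST, MLD, SIC, CHLA, current U/V, wind U/V) are
smooth analytic surfaces plus noise on regular lon/lat/time grids, with a
weak eastward mean current (0.11 m/s) and prevailing westerly winds.

Everything is driven by a single integer seed; the same config yields
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .geo import bearing_deg, haversine_km, normalize_lon

COLONY_LON = 51.86
COLONY_LAT = -46.43

__all__ = [
    "COLONY_LON",
    "COLONY_LAT",
    "ClusterParams",
    "SimConfig",
    "TABLE1_JUVENILE",
    "TABLE1_NONBREEDER",
    "simulate_track",
    "simulate_dives",
    "simulate_env",
    "simulate_dataset",
    "simulate_hourly_records",
]


@dataclass(frozen=True)
class ClusterParams:
    """Mean/SD of the four dive-hour variables for one behavioral cluster."""

    depth: tuple[float, float]  # m
    duration: tuple[float, float]  # s
    surface: tuple[float, float]  # s
    speed: tuple[float, float]  # km/h
    proportion: float  # share of hourly records
    mode: str  # 'traveling' or 'foraging'


# Published summary statistics for the three dive clusters of each stage.
TABLE1_JUVENILE = (
    ClusterParams((37.1, 31.8), (141.2, 56.6), (41.4, 22.9), (2.7, 0.7), 0.3, "traveling"),
    ClusterParams((31.0, 28.9), (120.7, 59.0), (57.1, 40.1), (1.1, 0.5), 0.4, "foraging"),
    ClusterParams((144.7, 42.9), (280.3, 59.2), (97.9, 37.4), (1.4, 0.8), 0.3, "foraging"),
)
TABLE1_NONBREEDER = (
    ClusterParams((37.2, 40.6), (156.0, 65.9), (38.6, 21.6), (3.6, 0.9), 0.3, "traveling"),
    ClusterParams((30.3, 34.6), (123.5, 67.9), (65.9, 49.0), (1.4, 0.7), 0.3, "foraging"),
    ClusterParams((170.8, 48.2), (316.5, 58.0), (90.3, 28.0), (1.5, 0.9), 0.4, "foraging"),
)


@dataclass
class SimConfig:
    """Study-level simulation configuration. Defaults are the study conditions."""

    seed: int = 0
    n_juveniles: int = 17
    n_nonbreeders: int = 6
    start_date: dict = field(
        default_factory=lambda: {"juvenile": "2013-12-01", "nonbreeder": "2014-03-01"}
    )
    duration_days_mean: dict = field(
        default_factory=lambda: {"juvenile": 206.0, "nonbreeder": 220.0}
    )
    duration_days_sd: dict = field(default_factory=lambda: {"juvenile": 30.0, "nonbreeder": 30.0})
    duration_days_min: float = 150.0
    fixes_per_day_mean: float = 14.5
    min_fix_gap_hours: float = 1.0
    dive_duty_cycle: tuple = (1, 2)  # 1 day ON, 2 days OFF
    dives_per_recording_day_mean: float = 55.0
    # phase schedule, days since individual departure
    transit_start_day: float = 90.0
    transit_duration_days: float = 45.0
    phase_jitter_days: float = 10.0
    # correlated-random-walk parameters, km/h mean speed per phase
    encamp_speed_kmh: float = 1.8
    transit_speed_kmh: float = 3.6
    max_step_speed_kmh: float = 7.0
    transit_bearing_deg: float = 235.0
    encamp_radius_km: float = 250.0
    # Argos error model
    argos_noise_sd_km: float = 1.5
    argos_noise_max_sd: float = 2.0  # truncation, in SD units
    outlier_rate: float = 0.05
    outlier_jump_km: float = 150.0
    # dive regime Markov chain (hourly), coupled to the movement phase:
    # transit hours are mostly traveling dives, encamped hours mostly
    # foraging, with overall time split ~30/70 as in the field data
    regime_p_tf_encamp: float = 1.0 / 6.0  # traveling -> foraging, encamped
    regime_p_ft_encamp: float = 0.0366
    regime_p_tf_transit: float = 1.0 / 12.0
    regime_p_ft_transit: float = 0.25
    mode_params: dict = field(
        default_factory=lambda: {"juvenile": TABLE1_JUVENILE, "nonbreeder": TABLE1_NONBREEDER}
    )
    # environment grid
    env_res_deg: float = 2.0
    env_time_step_days: int = 3
    current_mean_ms: float = 0.11
    wind_mean_ms: float = 8.0
    wind_toward_deg: float = 90.0  # prevailing westerlies blow toward the east
    sst_noise_sd: float = 0.3
    n_chla_patches: int = 12

    def physical_max_speed_kmh(self) -> float:
        """Largest implied fix-to-fix speed possible without outliers."""
        noise_reach = 2.0 * self.argos_noise_max_sd * self.argos_noise_sd_km
        return self.max_step_speed_kmh + noise_reach / self.min_fix_gap_hours

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mode_params"] = {
            stage: [dataclasses.asdict(c) for c in params]
            for stage, params in self.mode_params.items()
        }
        return d


def _truncnorm(rng, mean, sd, low, n=None, max_sd=4.0):
    """Normal draws re-sampled into [low, mean + max_sd*sd] (simple rejection)."""
    x = rng.normal(mean, sd, size=n)
    bad = (x < low) | (x > mean + max_sd * sd)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = (x < low) | (x > mean + max_sd * sd)
    return x


def _step_lonlat(lon, lat, bearing_deg_, dist_km):
    """Small planar step on the sphere (adequate for <20 km steps)."""
    b = np.radians(bearing_deg_)
    dlat = dist_km * np.cos(b) / 111.195  # km per degree latitude on R=6371 sphere
    dlon = dist_km * np.sin(b) / (111.195 * max(np.cos(np.radians(lat)), 0.05))
    return float(normalize_lon(lon + dlon)), float(np.clip(lat + dlat, -89.0, 89.0))


def simulate_track(
    cfg: SimConfig, individual_id: str, stage: str = "juvenile", rng=None, start_date=None
):
    """Simulate one individual's Argos fix series.

    Three movement phases (encamp / transit / encamp) are planted so that
    daily net squared displacement shows plateau-ramp-plateau. Returns a
    DataFrame with columns id, stage, timestamp, lon, lat plus the ground
    truth columns phase ({1,3,2}) and outlier (bool).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(start_date or cfg.start_date[stage])
    dur = float(
        _truncnorm(
            rng,
            cfg.duration_days_mean[stage],
            cfg.duration_days_sd[stage],
            cfg.duration_days_min,
        )
    )
    t_transit = cfg.transit_start_day + rng.uniform(-1, 1) * cfg.phase_jitter_days
    t_encamp2 = t_transit + cfg.transit_duration_days + rng.uniform(-1, 1) * cfg.phase_jitter_days
    if dur <= t_encamp2 + 20:
        dur = t_encamp2 + 60.0  # keep a usable final plateau

    # fix times: exponential gaps with a hard minimum, matching the target daily mean
    mean_gap = 24.0 / cfg.fixes_per_day_mean
    exp_mean = max(mean_gap - cfg.min_fix_gap_hours, 0.05)
    gaps, total = [], 0.0
    while total < dur * 24.0:
        g = cfg.min_fix_gap_hours + rng.exponential(exp_mean)
        gaps.append(g)
        total += g
    t_hours = np.concatenate([[0.0], np.cumsum(gaps)[:-1]])

    lon, lat = COLONY_LON, COLONY_LAT
    anchor1 = (COLONY_LON, COLONY_LAT)
    heading = rng.uniform(0, 360)
    rows = []
    anchor2 = None
    for t in t_hours:
        day = t / 24.0
        if day < t_transit:
            phase, anchor, speed_mean = 1, anchor1, cfg.encamp_speed_kmh
        elif day < t_encamp2:
            phase, anchor, speed_mean = 3, None, cfg.transit_speed_kmh
        else:
            if anchor2 is None:
                anchor2 = (lon, lat)
            phase, anchor, speed_mean = 2, anchor2, cfg.encamp_speed_kmh
        rows.append((t, lon, lat, phase))
        # advance to the next fix
        i = len(rows) - 1
        dt = (t_hours[i + 1] - t) if i + 1 < len(t_hours) else 0.0
        if dt <= 0:
            continue
        speed = min(rng.gamma(4.0, speed_mean / 4.0), cfg.max_step_speed_kmh)
        if phase == 3:
            heading = (cfg.transit_bearing_deg + np.degrees(rng.vonmises(0.0, 12.0))) % 360
        else:
            d_anchor = float(haversine_km(lon, lat, anchor[0], anchor[1]))
            if d_anchor > cfg.encamp_radius_km:
                heading = (
                    float(bearing_deg(lon, lat, anchor[0], anchor[1]))
                    + np.degrees(rng.vonmises(0.0, 2.0))
                ) % 360
            else:
                heading = (heading + np.degrees(rng.vonmises(0.0, 0.6))) % 360
        lon, lat = _step_lonlat(lon, lat, heading, speed * dt)

    df = pd.DataFrame(rows, columns=["t_hours", "lon_true", "lat_true", "phase"])
    # Argos jitter: truncated isotropic Gaussian in km
    n = len(df)
    r = np.minimum(
        np.abs(rng.normal(0.0, cfg.argos_noise_sd_km, n)),
        cfg.argos_noise_max_sd * cfg.argos_noise_sd_km,
    )
    theta = rng.uniform(0, 360, n)
    outlier = rng.random(n) < cfg.outlier_rate
    outlier[0] = outlier[-1] = False  # endpoints are exempt from filtering
    r = np.where(outlier, cfg.outlier_jump_km, r)
    lons, lats = [], []
    for j in range(n):
        lo, la = _step_lonlat(df.lon_true[j], df.lat_true[j], theta[j], r[j])
        lons.append(lo)
        lats.append(la)
    out = pd.DataFrame(
        {
            "id": individual_id,
            "stage": stage,
            "timestamp": start + pd.to_timedelta(df.t_hours, unit="h"),
            "lon": lons,
            "lat": lats,
            "phase": df.phase,
            "outlier": outlier,
        }
    )
    out["timestamp"] = out["timestamp"].dt.round("s")
    # rounding can collide timestamps drawn closer than 1 s apart
    out = out[~out["timestamp"].duplicated()].reset_index(drop=True)
    return out


def _draw_cluster_dive(rng, c: ClusterParams):
    depth = float(_truncnorm(rng, *c.depth, low=2.05))
    duration = float(_truncnorm(rng, *c.duration, low=15.0))
    surface = float(_truncnorm(rng, *c.surface, low=5.0))
    return depth, duration, surface


def simulate_dives(cfg: SimConfig, track: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Simulate transmitted dive summaries for one individual's track.

    Dives occur only on ON days of the 1-ON/2-OFF duty cycle (day index
    counted from departure). Each hour of an ON day belongs to a traveling
    or foraging regime following the configured Markov chain; traveling
    hours draw dives from cluster 1, foraging hours from the mixture of
    clusters 2 and 3. All depths exceed the 2 m recording threshold.

    Returns columns: id, start (timestamp), max_depth_m, duration_s,
    surface_s, plus ground truth regime ('traveling'/'foraging') and cluster.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    stage = track["stage"].iloc[0] if "stage" in track.columns else "juvenile"
    params = cfg.mode_params[stage]
    p23 = np.array([params[1].proportion, params[2].proportion], dtype=float)
    p23 /= p23.sum()
    on, off = cfg.dive_duty_cycle
    cycle = on + off
    start = track["timestamp"].min().normalize()
    end = track["timestamp"].max()
    n_days = int((end - start).days) + 1

    # per-day movement phase (1 encamp / 3 transit / 2 encamp) steers the regime chain
    day_idx = ((track["timestamp"] - start).dt.total_seconds() // 86400).astype(int)
    phase_by_day = track.groupby(day_idx)["phase"].agg(lambda s: s.mode().iloc[0])

    regime = 1 if rng.random() < 0.3 else 0  # 1 = traveling, drawn near stationarity
    rows = []
    for day in range(n_days):
        phase = int(phase_by_day.get(day, phase_by_day.iloc[-1]))
        if phase == 3:
            p_tf, p_ft = cfg.regime_p_tf_transit, cfg.regime_p_ft_transit
        else:
            p_tf, p_ft = cfg.regime_p_tf_encamp, cfg.regime_p_ft_encamp
        # regime chain runs over all hours so OFF days advance the state too
        day_regimes = []
        for _ in range(24):
            u = rng.random()
            if regime == 1:
                regime = 0 if u < p_tf else 1
            else:
                regime = 1 if u < p_ft else 0
            day_regimes.append(regime)
        if (day % cycle) >= on:
            continue  # OFF day: recorded dives are not transmitted
        n_dives = rng.poisson(cfg.dives_per_recording_day_mean)
        offsets = np.sort(rng.uniform(0, 24 * 3600.0, n_dives))
        for s in offsets:
            hour = int(s // 3600)
            trav = day_regimes[hour] == 1
            ci = 0 if trav else 1 + rng.choice(2, p=p23)
            depth, duration, surface = _draw_cluster_dive(rng, params[ci])
            rows.append(
                (
                    track["id"].iloc[0],
                    start + pd.Timedelta(days=day) + pd.Timedelta(seconds=round(s)),
                    depth,
                    duration,
                    surface,
                    "traveling" if trav else "foraging",
                    ci + 1,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["id", "start", "max_depth_m", "duration_s", "surface_s", "regime", "cluster"],
    )
    # second-rounded start times can collide for near-simultaneous draws
    return out[~out["start"].duplicated()].reset_index(drop=True)


def simulate_env(cfg: SimConfig, bbox, dates, rng=None) -> xr.Dataset:
    """Generate gridded environmental fields over ``bbox`` = (lon0, lon1, lat0, lat1).

    SST: meridional gradient (colder poleward) + noise. MLD: deepens in
    austral winter. SIC: nonzero only south of ~58°S. CHLA: positive sum of
    Gaussian patches over a low background. Current (uo, vo): weak eastward
    mean with smooth meanders. Wind (u10, v10): prevailing direction with
    synoptic variability.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lon0, lon1, lat0, lat1 = bbox
    lons = np.arange(lon0, lon1 + 1e-9, cfg.env_res_deg)
    lats = np.arange(lat0, lat1 + 1e-9, cfg.env_res_deg)
    dates = pd.to_datetime(dates)
    times = pd.date_range(dates.min().normalize(), dates.max().normalize() + pd.Timedelta(days=1),
                          freq=f"{cfg.env_time_step_days}D")
    nt, ny, nx = len(times), len(lats), len(lons)
    LAT = lats[None, :, None]
    LON = lons[None, None, :]
    doy = times.dayofyear.to_numpy()[:, None, None]
    season = np.cos(2 * np.pi * (doy - 15) / 365.25)  # +1 mid-summer (January)

    sst = 5.0 + 0.45 * (LAT + 50.0) + 1.5 * season + cfg.sst_noise_sd * rng.standard_normal(
        (nt, ny, nx)
    )
    mld = np.clip(
        90.0 - 55.0 * season - 1.2 * (LAT + 50.0) + 5.0 * rng.standard_normal((nt, ny, nx)),
        10.0,
        None,
    )
    sic = np.clip(-8.0 * (LAT + 58.0) * (1.0 - 0.8 * season), 0.0, 100.0) * (LAT < -58.0)
    sic = np.broadcast_to(sic, (nt, ny, nx)).copy()

    chla = np.full((nt, ny, nx), 0.08)
    for _ in range(cfg.n_chla_patches):
        clon = rng.uniform(lon0, lon1)
        clat = rng.uniform(lat0, lat1)
        amp = rng.uniform(0.3, 1.5)
        slon = rng.uniform(2.0, 6.0)
        slat = rng.uniform(1.5, 4.0)
        chla += amp * np.exp(
            -0.5 * (((LON - clon) / slon) ** 2 + ((LAT - clat) / slat) ** 2)
        ) * (0.75 + 0.25 * season)

    uo = cfg.current_mean_ms + 0.05 * np.sin(2 * np.pi * (LAT - lat0) / 14.0) * np.cos(
        2 * np.pi * (LON - lon0) / 30.0
    )
    vo = 0.04 * np.sin(2 * np.pi * (LON - lon0) / 24.0)
    uo = np.broadcast_to(uo, (nt, ny, nx)).copy()
    vo = np.broadcast_to(vo, (nt, ny, nx)).copy()

    wdir = np.radians(cfg.wind_toward_deg)
    u10 = cfg.wind_mean_ms * np.sin(wdir) + 2.0 * rng.standard_normal((nt, 1, 1)) + 1.0 * np.sin(
        2 * np.pi * (LAT - lat0) / 20.0
    )
    v10 = cfg.wind_mean_ms * np.cos(wdir) + 2.0 * rng.standard_normal((nt, 1, 1)) + 0.5 * np.cos(
        2 * np.pi * (LON - lon0) / 40.0
    )
    u10 = np.broadcast_to(u10, (nt, ny, nx)) + np.zeros((nt, ny, nx))
    v10 = np.broadcast_to(v10, (nt, ny, nx)) + np.zeros((nt, ny, nx))

    data = {
        "sst": sst,
        "mld": mld,
        "sic": sic,
        "chla": chla,
        "uo": uo,
        "vo": vo,
        "u10": u10,
        "v10": v10,
    }
    units = {
        "sst": "degC",
        "mld": "m",
        "sic": "%",
        "chla": "mg m-3",
        "uo": "m s-1",
        "vo": "m s-1",
        "u10": "m s-1",
        "v10": "m s-1",
    }
    ds = xr.Dataset(
        {
            k: (("time", "lat", "lon"), v.astype(np.float32), {"units": units[k]})
            for k, v in data.items()
        },
        coords={"time": times, "lat": lats, "lon": lons},
    )
    ds.attrs["convention_uv"] = "toward"  # vectors point in the direction of flow
    return ds


def simulate_dataset(cfg: SimConfig):
    """Generate the full study bundle.

    Returns ``(tracks, dives, env, manifest)``: all individuals' fix series
    (with ground-truth columns), all transmitted dive summaries, the gridded
    environmental fields, and a manifest echoing the configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    tracks, dives = [], []
    # alternate individuals over the two field seasons so the year factor
    # is identifiable alongside stage
    specs = [
        ("J%02d" % (i + 1), "juvenile", i % 2) for i in range(cfg.n_juveniles)
    ] + [("N%02d" % (i + 1), "nonbreeder", i % 2) for i in range(cfg.n_nonbreeders)]
    for ind, stage, cohort in specs:
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        start = pd.Timestamp(cfg.start_date[stage]) + pd.Timedelta(days=365 * cohort)
        tr = simulate_track(cfg, ind, stage, rng=sub_rng, start_date=start)
        tr["year"] = str(pd.Timestamp(cfg.start_date[stage]).year + cohort)
        dv = simulate_dives(cfg, tr, rng=sub_rng)
        tracks.append(tr)
        dives.append(dv)
    specs = [(ind, stage) for ind, stage, _ in specs]
    tracks = pd.concat(tracks, ignore_index=True)
    dives = pd.concat(dives, ignore_index=True)
    pad = 4.0
    bbox = (
        float(np.floor(tracks.lon.min() - pad)),
        float(np.ceil(tracks.lon.max() + pad)),
        float(max(np.floor(tracks.lat.min() - pad), -85.0)),
        float(min(np.ceil(tracks.lat.max() + pad), 0.0)),
    )
    env = simulate_env(cfg, bbox, tracks["timestamp"], rng=np.random.default_rng(cfg.seed + 1))
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "individuals": {ind: stage for ind, stage in specs},
        "bbox": list(bbox),
        "notes": [
            "fix times: exponential inter-fix gaps with a hard minimum, tuned to the daily mean",
        ],
    }
    return tracks, dives, env, manifest


def simulate_hourly_records(
    params=TABLE1_JUVENILE, n: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Draw hourly dive/speed records directly from the cluster mixture.

    Used to test the clustering stage against known labels: each record is a
    4-variable draw (depth m, duration s, surface s, speed km/h) from one of
    the three cluster distributions, chosen with the published allocated-time
    proportions. Returns the records with their true cluster labels.
    """
    rng = np.random.default_rng(seed)
    props = np.array([c.proportion for c in params], dtype=float)
    props /= props.sum()
    labels = rng.choice(len(params), size=n, p=props)
    rows = []
    for lab in labels:
        c = params[lab]
        depth, duration, surface = _draw_cluster_dive(rng, c)
        speed = float(_truncnorm(rng, *c.speed, low=0.0))
        rows.append((depth, duration, surface, speed, lab + 1))
    return pd.DataFrame(
        rows, columns=["depth_m", "duration_s", "surface_s", "speed_kmh", "true_cluster"]
    )
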