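"""End-to-end pipeline: simulate → filter → segment → modes → habitat → orient.

Every stage reads and writes files, so any stage can be rerun on its own;
all randomness flows from configured seeds. Stage functions log input and
output counts and return their main products for programmatic use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dive_modes as dm
from . import filtering, io, nsd, orientation
from .geo import laea_xy
from .habitat import aic_dredge, fit_binomial_gamm, sample_env, season_of
from .simulate import COLONY_LAT, COLONY_LON, SimConfig, simulate_dataset

log = logging.getLogger("pengmove")

DEFAULT_CONFIG = {
    "seed": 0,
    "vmax_kmh": 14.0,
    "k_clusters": 3,
    "min_track_days": 120,
    "hmm_restarts": 10,
    "habitat": {
        "covariates": ["sst", "mld", "chla", "curr_speed", "wind_speed"],
        "spatial": True,
        "dredge": False,
        "n_basis": 10,
        "max_obs": 8000,
    },
    "orientation": {"media": ["wind", "current"], "uv_convention": "toward"},
}


class ConfigError(KeyError):
    pass


def _cfg_get(config: dict, key: str):
    cur = config
    for part in key.split("."):
        if not isinstance(cur, dict) or part not in cur:
            raise ConfigError(f"missing config key: {key!r}")
        cur = cur[part]
    return cur


def merge_config(user: dict | None) -> dict:
    def merge(a, b):
        out = dict(a)
        for k, v in (b or {}).items():
            out[k] = merge(a[k], v) if isinstance(v, dict) and isinstance(a.get(k), dict) else v
        return out

    return merge(DEFAULT_CONFIG, user or {})


def stage_simulate(config: dict, outdir) -> io.StudyBundle:
    """Generate and write the synthetic study bundle."""
    seed = _cfg_get(config, "seed")
    sim_kwargs = config.get("simulate", {})
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(sim_kwargs) - fields
    if unknown:
        raise ConfigError(f"unknown simulate config keys: {sorted(unknown)}")
    cfg = SimConfig(seed=seed, **sim_kwargs)
    tracks, dives, env, manifest = simulate_dataset(cfg)
    log.info("simulate: %d fixes, %d dives", len(tracks), len(dives))
    return io.write_bundle(tracks, dives, env, manifest, outdir)


def stage_filter(tracks_path, out_path, report_path=None, vmax: float = 14.0):
    tracks = io.read_tracks(tracks_path)
    filt, rep = filtering.filter_dataset(tracks, vmax=vmax)
    log.info(
        "filter: %d in, %d removed (%.1f%%), %d out",
        rep.n_input, rep.n_removed, 100 * rep.removed_fraction, len(filt),
    )
    io.write_tracks(filt, out_path)
    if report_path:
        with open(report_path, "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1)
    return filt, rep


def stage_segment(
    filtered_path,
    out_path,
    grid_path=None,
    env_path=None,
    pca_path=None,
    min_track_days: int = 120,
    n_restarts: int = 10,
    seed: int = 0,
):
    """NSD + latent states per individual; winter range; optional winter PCA.

    Individuals tracked for fewer than ``min_track_days`` days are excluded
    from segmentation (short deployments cannot express the three phases).
    """
    tracks = io.read_tracks(filtered_path)
    out, excluded = [], []
    for ind, sub in tracks.groupby("id", sort=True):
        days = (sub["timestamp"].max() - sub["timestamp"].min()).days
        if days < min_track_days:
            excluded.append(ind)
            continue
        daily = nsd.daily_mean_locations(sub)
        series = nsd.compute_nsd(daily)
        model = nsd.fit_latent_states(series, n_restarts=n_restarts, seed=seed)
        dec = nsd.decode_states(model, series)
        if "stage" in sub.columns:
            dec["stage"] = sub["stage"].iloc[0]
        out.append(dec)
    if excluded:
        log.info("segment: excluded %d short deployments: %s", len(excluded), excluded)
    if not out:
        raise RuntimeError("no individual long enough for segmentation")
    states = pd.concat(out, ignore_index=True)
    states_out = states.copy()
    states_out["date"] = pd.to_datetime(states_out["date"]).dt.strftime("%Y-%m-%d")
    states_out.to_csv(out_path, index=False, float_format="%.6f")
    log.info("segment: %d individual-days, %d state-2", len(states), int((states.state == 2).sum()))
    if grid_path:
        grid = nsd.winter_range(states)
        grid.to_csv(grid_path, index=False, float_format="%.2f")
    pca = None
    if env_path and pca_path:
        env = io.read_env(env_path)
        s2 = states[states["state"] == 2]
        mat = pd.DataFrame(
            {
                "sst": sample_env(env, s2.lon, s2.lat, s2.date, "sst"),
                "mld": sample_env(env, s2.lon, s2.lat, s2.date, "mld"),
                "sic": sample_env(env, s2.lon, s2.lat, s2.date, "sic"),
                "chla": sample_env(env, s2.lon, s2.lat, s2.date, "chla"),
                "curr_speed": np.hypot(
                    sample_env(env, s2.lon, s2.lat, s2.date, "uo"),
                    sample_env(env, s2.lon, s2.lat, s2.date, "vo"),
                ),
                "wind_speed": np.hypot(
                    sample_env(env, s2.lon, s2.lat, s2.date, "u10"),
                    sample_env(env, s2.lon, s2.lat, s2.date, "v10"),
                ),
            }
        )
        loadings, scores, var = nsd.winter_env_pca(mat)
        pca = {
            "variance_fraction": [float(v) for v in var],
            "loadings": {c: [float(x) for x in loadings[c]] for c in loadings.columns},
            "variables": list(loadings.index),
            "n_rows": int(len(mat.dropna())),
        }
        with open(pca_path, "w") as fh:
            json.dump(pca, fh, indent=1)
    return states, pca


def stage_modes(dives_path, filtered_path, out_path, summary_path=None, k: int = 3):
    """Hourly aggregation + clustering + mode labels, separately per stage."""
    dives = io.read_dives(dives_path)
    tracks = io.read_tracks(filtered_path)
    stage_map = (
        tracks.groupby("id")["stage"].first()
        if "stage" in tracks.columns
        else pd.Series(dtype=object)
    )
    parts, summaries = [], {}
    dives = dives.copy()
    dives["stage"] = dives["id"].map(stage_map).fillna("all")
    for stage, dsub in dives.groupby("stage", sort=True):
        located = []
        for ind, isub in dsub.groupby("id", sort=True):
            tr = tracks[tracks["id"] == ind]
            if len(tr) < 2:
                continue
            located.append(dm.assign_dive_locations(isub, tr))
        if not located:
            continue
        located = pd.concat(located, ignore_index=True)
        speeds = dm.dive_travel_speed(located)
        hourly = dm.hourly_aggregate(speeds)
        hourly["stage"] = stage
        labels, _, summary = dm.cluster_hourly(hourly, k=k)
        summary = dm.label_modes(summary)
        hourly["cluster_label"] = labels
        hourly["mode"] = [summary.modes[c] for c in labels]
        parts.append(hourly)
        summaries[stage] = summary.to_dict()
    if not parts:
        raise RuntimeError("no dive records could be located on tracks")
    out = pd.concat(parts, ignore_index=True)
    out_w = out.copy()
    out_w["hour"] = pd.to_datetime(out_w["hour"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out_w.to_csv(out_path, index=False, float_format="%.4f")
    log.info("modes: %d hourly records (%s)", len(out), {s: len(p) for s, p in zip(summaries, parts)})
    if summary_path:
        with open(summary_path, "w") as fh:
            json.dump(summaries, fh, indent=1, default=str)
    return out, summaries


def build_habitat_observations(hourly: pd.DataFrame, env, tracks: pd.DataFrame) -> pd.DataFrame:
    """Join hourly mode records with environmental covariates and factors."""
    obs = hourly.copy()
    t = pd.to_datetime(obs["hour"])
    for var in ("sst", "mld", "sic", "chla"):
        obs[var] = sample_env(env, obs.lon, obs.lat, t, var)
    obs["curr_speed"] = np.hypot(
        sample_env(env, obs.lon, obs.lat, t, "uo"), sample_env(env, obs.lon, obs.lat, t, "vo")
    )
    obs["wind_speed"] = np.hypot(
        sample_env(env, obs.lon, obs.lat, t, "u10"), sample_env(env, obs.lon, obs.lat, t, "v10")
    )
    x, y = laea_xy(obs["lon"].to_numpy(), obs["lat"].to_numpy(), (COLONY_LON, COLONY_LAT))
    obs["x_km"], obs["y_km"] = x, y
    obs["season"] = season_of(t).to_numpy()
    if "year" in tracks.columns:
        obs["year"] = obs["id"].map(tracks.groupby("id")["year"].first().astype(str))
    obs["y"] = (obs["mode"] == "foraging").astype(float)
    n0 = len(obs)
    obs = obs.dropna(subset=["sst", "mld", "chla", "curr_speed", "wind_speed"]).reset_index(
        drop=True
    )
    if n0 - len(obs):
        log.info("habitat: %d records outside environmental grid dropped", n0 - len(obs))
    return obs


def stage_habitat(
    modes_path,
    env_path,
    tracks_path,
    fit_path,
    table_path=None,
    config: dict | None = None,
    seed: int = 0,
):
    cfg = (config or {}).get("habitat", DEFAULT_CONFIG["habitat"])
    hourly = pd.read_csv(modes_path, parse_dates=["hour"])
    env = io.read_env(env_path)
    tracks = io.read_tracks(tracks_path)
    obs = build_habitat_observations(hourly, env, tracks)
    factors = tuple(f for f in ("year", "stage", "season") if f in obs and obs[f].nunique() > 1)
    if len(obs) > cfg["max_obs"]:
        # deterministic thinning keeps fits tractable on one CPU
        obs = obs.iloc[np.linspace(0, len(obs) - 1, cfg["max_obs"]).round().astype(int)]
        obs = obs.reset_index(drop=True)
    covs = tuple(cfg["covariates"])
    if cfg.get("dredge"):
        table, fit = aic_dredge(
            obs, covs, factors=factors, include_spatial=cfg.get("spatial", True), random="id",
            n_basis=cfg.get("n_basis", 10),
        )
        if table_path:
            table.to_csv(table_path, index=False, float_format="%.4f")
    else:
        fit = fit_binomial_gamm(
            obs,
            smooths=covs,
            factors=factors,
            spatial=cfg.get("spatial", True),
            random="id",
            n_basis=cfg.get("n_basis", 10),
        )
        if table_path:
            pd.DataFrame(
                [{"terms": "+".join(covs), "logLik": fit.loglik, "edf": fit.edf_total, "AIC": fit.aic}]
            ).to_csv(table_path, index=False, float_format="%.4f")
    summary = {
        "n_obs": int(len(obs)),
        "terms": list(covs),
        "factors": list(factors),
        "loglik": fit.loglik,
        "edf_total": fit.edf_total,
        "aic": fit.aic,
        "lambda": fit.lambda_by_term(),
        "random_intercept_sd": fit.random_intercept_sd,
        "edf_by_term": fit.edf_by_term,
        "converged": fit.converged,
    }
    with open(fit_path, "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("habitat: fit on %d obs, AIC %.1f", len(obs), fit.aic)
    return fit, obs


def stage_orient(
    filtered_path,
    env_path,
    out_path,
    table_path=None,
    glmm_path=None,
    media=("wind", "current"),
    uv_convention: str = "toward",
):
    tracks = io.read_tracks(filtered_path)
    env = io.read_env(env_path)
    recs = []
    for medium in media:
        r = orientation.build_orientation_records(
            tracks, env, medium=medium, uv_convention=uv_convention
        )
        recs.append(r)
    records = pd.concat(recs, ignore_index=True)
    out_w = records.copy()
    out_w["start"] = pd.to_datetime(out_w["start"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out_w.to_csv(out_path, index=False, float_format="%.4f")
    table = orientation.proportion_table(records)
    if table_path:
        table.to_csv(table_path, index=False, float_format="%.4f")
    glmm_out = {}
    for medium in media:
        sub = records[records["medium"] == medium]
        try:
            res = orientation.compare_proportions(sub)
            glmm_out[medium] = {
                "cells": res["cells"],
                "beta": [float(b) for b in res["fit"].beta],
                "sigma": res["fit"].sigma,
                "loglik": res["fit"].loglik,
                "letters": res["letters"],
                "contrasts": res["contrasts"].to_dict(orient="records"),
            }
        except ValueError as e:
            glmm_out[medium] = {"error": str(e)}
    if glmm_path:
        with open(glmm_path, "w") as fh:
            json.dump(glmm_out, fh, indent=1, default=float)
    log.info("orient: %d records (%d media)", len(records), len(media))
    return records, table, glmm_out


def run_all(config: dict | None, outdir, simulate: bool = True, indir=None):
    """Run the whole pipeline; every stage writes its outputs under ``outdir``."""
    config = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = _cfg_get(config, "seed")
    stage_name = "simulate"
    try:
        if simulate:
            bundle = stage_simulate(config, outdir)
        else:
            bundle = io.read_bundle(indir or outdir)
        stage_name = "filter"
        stage_filter(
            bundle.tracks_path,
            outdir / "tracks_filtered.csv",
            outdir / "filter_report.json",
            vmax=_cfg_get(config, "vmax_kmh"),
        )
        stage_name = "segment"
        stage_segment(
            outdir / "tracks_filtered.csv",
            outdir / "nsd_states.csv",
            outdir / "winter_grid.csv",
            bundle.env_path,
            outdir / "winter_pca.json",
            min_track_days=_cfg_get(config, "min_track_days"),
            n_restarts=_cfg_get(config, "hmm_restarts"),
            seed=seed,
        )
        stage_name = "modes"
        stage_modes(
            bundle.dives_path,
            outdir / "tracks_filtered.csv",
            outdir / "hourly_modes.csv",
            outdir / "cluster_summary.json",
            k=_cfg_get(config, "k_clusters"),
        )
        stage_name = "habitat"
        stage_habitat(
            outdir / "hourly_modes.csv",
            bundle.env_path,
            outdir / "tracks_filtered.csv",
            outdir / "habitat_fit.json",
            outdir / "habitat_models.csv",
            config=config,
            seed=seed,
        )
        stage_name = "orient"
        stage_orient(
            outdir / "tracks_filtered.csv",
            bundle.env_path,
            outdir / "orientation.csv",
            outdir / "orientation_table.csv",
            outdir / "orientation_glmm.json",
            media=tuple(_cfg_get(config, "orientation.media")),
            uv_convention=_cfg_get(config, "orientation.uv_convention"),
        )
    except ConfigError:
        raise
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage_name}' failed: {e}") from e
    return outdir
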