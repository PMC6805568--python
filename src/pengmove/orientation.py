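"""Orientation of 12-h movement segments relative to wind and current.

Tracks are re-interpolated at 12-h intervals; the heading of each segment
is differenced against the direction the medium (wind or ocean current)
flows toward, sampled at the segment start. The angular difference is
binned: within ±45° of the flow = 'similar' (downstream), within ±45° of
its opposite = 'against' (upstream), everything else = 'cross'
(perpendicular). For isotropic headings these bins cover 25% / 25% / 50%
of the circle.

Seasonal/stage differences in the upstream-vs-downstream split are tested
with a binomial random-intercept GLMM (individual as random effect) fitted
by adaptive Gauss-Hermite quadrature, followed by Bonferroni-adjusted
pairwise cell comparisons summarized as compact letters. The influence of
ocean productivity along the track is modeled by reusing the habitat
module's penalized spline machinery with smooths of CHLA at the current
(t) and next (t+1) segment locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .geo import angular_difference, bearing_deg, interpolate_regular
from .habitat import fit_binomial_gamm, sample_env, season_of

__all__ = [
    "classify_direction",
    "build_orientation_records",
    "proportion_table",
    "MixedLogitFit",
    "fit_mixed_logit",
    "compare_proportions",
    "fit_chla_orientation",
]


def classify_direction(delta) -> np.ndarray:
    """Bin angular differences (degrees in [0, 360)) into orientation classes.

    'similar' on [315, 360) and [0, 45]; 'against' on [135, 225]; 'cross'
    elsewhere. Boundary membership follows the closed bins as printed
    (a measure-zero convention).
    """
    d = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any((d < 0) | (d >= 360)):
        raise ValueError("delta must lie in [0, 360)")
    out = np.full(d.shape, "cross", dtype=object)
    out[(d >= 315.0) | (d <= 45.0)] = "similar"
    out[(d >= 135.0) & (d <= 225.0)] = "against"
    return out if np.ndim(delta) else out.item()


def build_orientation_records(
    tracks: pd.DataFrame,
    env,
    medium: str = "wind",
    step_hours: float = 12.0,
    uv_convention: str = "toward",
    seasons: dict | None = None,
) -> pd.DataFrame:
    """12-h segment headings vs flow direction, with CHLA at t and t+1.

    ``medium`` selects the flow field: 'wind' uses u10/v10, 'current' uses
    uo/vo. ``uv_convention`` declares whether the U/V components point in
    the direction the medium flows toward ('toward', the model-output
    convention) or comes from ('from', the meteorological convention, which
    is rotated by 180°). Zero-length segments and zero flow vectors are
    skipped (counts in ``attrs``).
    """
    if medium not in ("wind", "current"):
        raise ValueError("medium must be 'wind' or 'current'")
    if uv_convention not in ("toward", "from"):
        raise ValueError("uv_convention must be 'toward' or 'from'")
    uvar, vvar = ("u10", "v10") if medium == "wind" else ("uo", "vo")
    rows = []
    n_zero_seg = n_zero_flow = 0
    for ind, sub in tracks.groupby("id", sort=True):
        sub = sub.sort_values("timestamp")
        if len(sub) < 2:
            continue
        ti = interpolate_regular(sub, step_hours=step_hours)
        if len(ti) < 2:
            continue
        stage = sub["stage"].iloc[0] if "stage" in sub.columns else None
        lon = ti["lon"].to_numpy()
        lat = ti["lat"].to_numpy()
        t = ti["timestamp"]
        same = (lon[:-1] == lon[1:]) & (lat[:-1] == lat[1:])
        heading = np.full(len(ti) - 1, np.nan)
        ok = ~same
        heading[ok] = bearing_deg(lon[:-1][ok], lat[:-1][ok], lon[1:][ok], lat[1:][ok])
        n_zero_seg += int(same.sum())

        u = sample_env(env, lon[:-1], lat[:-1], t.iloc[:-1], uvar)
        v = sample_env(env, lon[:-1], lat[:-1], t.iloc[:-1], vvar)
        if uv_convention == "from":
            u, v = -u, -v
        speed = np.hypot(u, v)
        flow_toward = np.degrees(np.arctan2(u, v)) % 360.0  # u east, v north
        zero_flow = speed < 1e-12
        n_zero_flow += int(np.nansum(zero_flow))

        chla_t = sample_env(env, lon[:-1], lat[:-1], t.iloc[:-1], "chla")
        chla_t1 = sample_env(env, lon[1:], lat[1:], t.iloc[1:], "chla")

        keep = ok & ~zero_flow & np.isfinite(u) & np.isfinite(v)
        d = pd.DataFrame(
            {
                "id": ind,
                "stage": stage,
                "start": t.iloc[:-1].to_numpy(),
                "heading": heading,
                "medium": medium,
                "flow_toward": flow_toward,
                "chla_t": chla_t,
                "chla_t1": chla_t1,
            }
        )[keep]
        rows.append(d)
    rec = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if len(rec):
        rec["delta"] = angular_difference(rec["heading"], rec["flow_toward"])
        rec["klass"] = classify_direction(rec["delta"].to_numpy())
        rec["season"] = season_of(rec["start"], seasons).to_numpy()
    rec.attrs["n_zero_segments"] = n_zero_seg
    rec.attrs["n_zero_flow"] = n_zero_flow
    return rec


def proportion_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD (across individuals) of class proportions per stage × season.

    Individual-level proportions are computed first so the SD reflects
    inter-individual spread; cells with a single individual report SD NaN
    and are flagged in ``attrs['flagged_cells']``.
    """
    klasses = ["against", "similar", "cross"]
    per_ind = (
        records.groupby(["stage", "season", "medium", "id"])["klass"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=klasses, fill_value=0.0)
    )
    rows, flagged = [], []
    for cell, sub in per_ind.groupby(level=["stage", "season", "medium"]):
        row = {"stage": cell[0], "season": cell[1], "medium": cell[2], "n_individuals": len(sub)}
        for k in klasses:
            row[f"{k}_mean"] = float(sub[k].mean())
            row[f"{k}_sd"] = float(sub[k].std(ddof=1)) if len(sub) > 1 else np.nan
        if len(sub) < 2:
            flagged.append(cell)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["flagged_cells"] = flagged
    return out


# ---------------------------------------------------------------------------
# binomial random-intercept GLMM by adaptive Gauss-Hermite quadrature


@dataclass
class MixedLogitFit:
    """ML fit of logit P(y=1) = x'beta + b_i, b_i ~ N(0, sigma^2)."""

    beta: np.ndarray
    names: list
    sigma: float
    loglik: float
    vcov: np.ndarray  # for beta only
    converged: bool
    n_obs: int
    n_groups: int


def _agh_loglik(theta, X, y, gidx, n_groups, nodes, weights, newton_iter=12):
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    eta0 = X @ beta
    b = np.zeros(n_groups)
    # per-group Newton for the conditional mode of b
    for _ in range(newton_iter):
        mu = expit(eta0 + b[gidx])
        g = np.bincount(gidx, weights=y - mu, minlength=n_groups) - b / sigma**2
        h = -np.bincount(gidx, weights=mu * (1 - mu), minlength=n_groups) - 1.0 / sigma**2
        step = g / h
        b -= np.clip(step, -5.0, 5.0)
    mu = expit(eta0 + b[gidx])
    h = -np.bincount(gidx, weights=mu * (1 - mu), minlength=n_groups) - 1.0 / sigma**2
    tau = 1.0 / np.sqrt(-h)  # curvature at the final mode
    # adaptive GH: sum_k w_k * exp(h(b + sqrt2 tau x_k) + x_k^2) * sqrt2 tau
    ll_groups = np.full(n_groups, -np.inf)
    contrib = np.zeros((len(nodes), n_groups))
    for k, (xk, wk) in enumerate(zip(nodes, weights)):
        bk = b + np.sqrt(2.0) * tau * xk
        eta = eta0 + bk[gidx]
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        hk = np.bincount(gidx, weights=ll_obs, minlength=n_groups) + norm.logpdf(
            bk, scale=sigma
        )
        contrib[k] = hk + xk**2 + np.log(wk)
    m = contrib.max(axis=0)
    ll_groups = m + np.log(np.exp(contrib - m).sum(axis=0)) + 0.5 * np.log(2.0) + np.log(tau)
    return float(ll_groups.sum())


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups,
    names=None,
    n_nodes: int = 9,
) -> MixedLogitFit:
    """Fit a binomial random-intercept GLMM by adaptive Gauss-Hermite ML.

    The per-individual integrals are 1-D, integrated with ``n_nodes``
    (>= 9) quadrature nodes centered and scaled at each group's conditional
    mode. The covariance of the fixed effects comes from the inverse of a
    numerical Hessian of the marginal log-likelihood at the optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, levels = pd.factorize(np.asarray(groups))
    n_groups = len(levels)
    nodes, weights = hermgauss(max(n_nodes, 9))
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]

    def nll(theta):
        return -_agh_loglik(theta, X, y, codes, n_groups, nodes, weights)

    theta0 = np.concatenate([np.zeros(X.shape[1]), [np.log(0.5)]])
    res = minimize(nll, theta0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    theta = res.x
    # numerical Hessian (central differences) for the covariance matrix
    p = len(theta)
    H = np.zeros((p, p))
    eps = 1e-4 * np.maximum(np.abs(theta), 1.0)
    for i in range(p):
        for j in range(i, p):
            ei = np.eye(p)[i] * eps[i]
            ej = np.eye(p)[j] * eps[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps[i] * eps[j])
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(H)
    return MixedLogitFit(
        beta=theta[:-1],
        names=names,
        sigma=float(np.exp(theta[-1])),
        loglik=float(-res.fun),
        vcov=vcov_full[:-1, :-1],
        converged=bool(res.success),
        n_obs=len(y),
        n_groups=n_groups,
    )


def _letters_from_pairs(cells, different: set) -> dict:
    """Compact letter display: cells sharing a letter are not sig. different."""
    groups: list[set] = []
    for c in cells:
        placed = False
        for g in groups:
            if all((c, o) not in different and (o, c) not in different for o in g):
                g.add(c)
                placed = True
        if not placed:
            groups.append({c})
    # absorb redundant groups
    groups = [g for i, g in enumerate(groups) if not any(g < h for j, h in enumerate(groups) if i != j)]
    letters = {c: "" for c in cells}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for c in g:
            letters[c] += letter
    return letters


def compare_proportions(records: pd.DataFrame, alpha: float = 0.05, n_nodes: int = 9):
    """Upstream-vs-downstream GLMM with Bonferroni pairwise cell contrasts.

    Cross-oriented segments are excluded; the response is upstream
    ('against') = 1 vs downstream ('similar') = 0. Cells are stage × season
    combinations, entered as a cell-mean parameterization so that pairwise
    contrasts are simple coefficient differences on the logit scale;
    individual is the random intercept. Returns a dict with the fit, the
    contrast table (Bonferroni-adjusted p-values) and compact letters per
    cell. Cells without response variation are reported non-estimable.
    """
    rec = records[records["klass"].isin(["against", "similar"])].copy()
    rec["cell"] = rec["stage"].astype(str) + ":" + rec["season"].astype(str)
    cells = sorted(rec["cell"].unique())
    if len(cells) < 2:
        raise ValueError("need at least 2 stage-season cells")
    y = (rec["klass"] == "against").to_numpy(dtype=float)
    X = np.column_stack([(rec["cell"] == c).to_numpy(dtype=float) for c in cells])
    fit = fit_mixed_logit(X, y, rec["id"].to_numpy(), names=cells, n_nodes=n_nodes)

    var_ok = rec.groupby("cell")["klass"].nunique() == 2
    pairs = [(a, b) for i, a in enumerate(cells) for b in cells[i + 1 :]]
    n_con = len(pairs)
    rows = []
    different = set()
    for a, b in pairs:
        ia, ib = cells.index(a), cells.index(b)
        est = fit.beta[ia] - fit.beta[ib]
        se = np.sqrt(fit.vcov[ia, ia] + fit.vcov[ib, ib] - 2 * fit.vcov[ia, ib])
        if not (var_ok.get(a, False) and var_ok.get(b, False)) or not np.isfinite(se) or se <= 0:
            rows.append({"a": a, "b": b, "estimate": est, "se": np.nan, "z": np.nan,
                         "p_raw": np.nan, "p_adj": np.nan, "estimable": False})
            continue
        z = est / se
        p_raw = 2.0 * norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_con)
        if p_adj < alpha:
            different.add((a, b))
        rows.append({"a": a, "b": b, "estimate": est, "se": se, "z": z,
                     "p_raw": p_raw, "p_adj": p_adj, "estimable": True})
    contrasts = pd.DataFrame(rows)
    letters = _letters_from_pairs(cells, different)
    return {"fit": fit, "contrasts": contrasts, "letters": letters, "cells": cells}


def fit_chla_orientation(records: pd.DataFrame, **kwargs):
    """Model upstream choice as smooth functions of CHLA at t and t+1.

    Reuses the habitat module's penalized binomial GAMM: response upstream
    ('against') = 1 vs downstream ('similar') = 0 (cross excluded), smooths
    of chla_t and chla_t1, stage and season factors, individual random
    intercept.
    """
    rec = records[records["klass"].isin(["against", "similar"])].copy()
    rec = rec.dropna(subset=["chla_t", "chla_t1"])
    rec["y"] = (rec["klass"] == "against").astype(float)
    factors = tuple(f for f in ("stage", "season") if rec[f].nunique() > 1)
    return fit_binomial_gamm(
        rec, smooths=("chla_t", "chla_t1"), factors=factors, random="id", **kwargs
    )
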