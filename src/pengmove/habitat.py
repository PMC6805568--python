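"""Binomial GAMM for habitat preference: P(foraging) vs environment.

The response is the behavioral mode of an hourly dive record (traveling = 0,
foraging = 1), modeled on the logit scale as a sum of penalized cubic
regression splines of environmental covariates (with shrinkage, so a term
can be penalized to zero), an optional 2-D tensor-product smooth of
Lambert-azimuthal-equal-area-projected coordinates, categorical fixed
effects (year, stage, season) and a per-individual random intercept.

Estimation is penalized iteratively re-weighted least squares (P-IRLS);
smoothing parameters — including the random-intercept precision — are
chosen by maximizing a Laplace approximation to the marginal likelihood
over a log-spaced grid with coordinate descent. The random intercept is a
ridge-penalized coefficient block (the standard random-effect-as-smooth
equivalence); its variance is 1/lambda. Model selection over covariate
subsets uses conditional AIC = -2 logLik + 2 * total effective df, with
effective df the trace of the influence matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import BSpline
from scipy.special import expit

__all__ = [
    "sample_env",
    "build_smooth_basis",
    "SmoothBasis",
    "GammFit",
    "fit_binomial_gamm",
    "aic_dredge",
    "predict_foraging",
    "season_of",
    "DEFAULT_SEASONS",
]

DEFAULT_SEASONS = {
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}


def season_of(timestamps, seasons: dict | None = None) -> pd.Series:
    """Austral season labels for timestamps (boundaries configurable)."""
    seasons = seasons or DEFAULT_SEASONS
    return pd.to_datetime(pd.Series(timestamps)).dt.month.map(seasons)


# ---------------------------------------------------------------------------
# environment sampling


def sample_env(env: xr.Dataset, lons, lats, times, var: str) -> np.ndarray:
    """Sample one field at given positions: bilinear in space, nearest time.

    Points outside the grid bounding box return NaN (callers exclude those
    rows and log the count).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    ts = pd.to_datetime(pd.Series(np.ravel(times)), utc=True).dt.tz_localize(None)
    t = ts.to_numpy().astype("datetime64[ns]")
    tgrid = pd.to_datetime(env["time"].values).to_numpy().astype("datetime64[ns]")
    ti = np.searchsorted(tgrid, t)
    ti = np.clip(ti, 1, len(tgrid) - 1)
    left_closer = np.abs(t - tgrid[ti - 1]) <= np.abs(tgrid[ti] - t)
    ti = np.where(left_closer, ti - 1, ti)

    da = env[var]
    out = np.full(lons.shape, np.nan)
    for k in np.unique(ti):
        sel = ti == k
        sl = da.isel(time=int(k))
        out[sel] = _bilinear(
            sl["lon"].values, sl["lat"].values, sl.values, lons[sel], lats[sel]
        )
    return out


def _bilinear(gx, gy, z, x, y):
    """Bilinear interpolation on a regular (lat, lon) grid; NaN outside."""
    out = np.full(np.shape(x), np.nan)
    inside = (x >= gx[0]) & (x <= gx[-1]) & (y >= gy[0]) & (y <= gy[-1])
    if not inside.any():
        return out
    xi = np.clip(np.searchsorted(gx, x[inside]) - 1, 0, len(gx) - 2)
    yi = np.clip(np.searchsorted(gy, y[inside]) - 1, 0, len(gy) - 2)
    fx = (x[inside] - gx[xi]) / (gx[xi + 1] - gx[xi])
    fy = (y[inside] - gy[yi]) / (gy[yi + 1] - gy[yi])
    z = np.asarray(z, dtype=float)
    v = (
        z[yi, xi] * (1 - fx) * (1 - fy)
        + z[yi, xi + 1] * fx * (1 - fy)
        + z[yi + 1, xi] * (1 - fx) * fy
        + z[yi + 1, xi + 1] * fx * fy
    )
    out[inside] = v
    return out


# ---------------------------------------------------------------------------
# spline bases


@dataclass
class SmoothBasis:
    """Cubic B-spline basis on quantile knots with a shrinkage penalty."""

    knots: np.ndarray  # full (augmented) knot vector
    degree: int = 3
    shrink: float = 1e-2

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @classmethod
    def from_data(cls, x, n_basis: int = 10, degree: int = 3, shrink: float = 1e-2):
        x = np.asarray(x, dtype=float)
        uniq = np.unique(x)
        nb = n_basis
        if len(uniq) < n_basis:
            nb = max(degree + 1, len(uniq))
            warnings.warn(
                f"only {len(uniq)} distinct values: basis reduced to {nb} functions"
            )
        n_interior = nb - degree - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(uniq, qs)
        else:
            interior = np.array([])
        lo, hi = float(uniq.min()), float(uniq.max())
        knots = np.concatenate(
            [[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        )
        return cls(knots=knots, degree=degree, shrink=shrink)

    def design(self, x) -> np.ndarray:
        """Raw basis matrix (rows sum to 1 inside the data range)."""
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        # nudge the right boundary inside so the last basis function is closed
        x = np.minimum(x, np.nextafter(self.knots[-1], -np.inf))
        B = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B

    def penalty(self) -> np.ndarray:
        """Squared-second-difference coefficient penalty plus a shrinkage ridge."""
        p = self.n_basis
        if p < 3:
            return np.eye(p)
        D2 = np.diff(np.eye(p), n=2, axis=0)
        return D2.T @ D2 + self.shrink * np.eye(p)


def build_smooth_basis(values, n_basis: int = 10):
    """Convenience wrapper: returns (basis_matrix, penalty, SmoothBasis)."""
    sb = SmoothBasis.from_data(values, n_basis=n_basis)
    return sb.design(values), sb.penalty(), sb


# ---------------------------------------------------------------------------
# model terms and fitting


@dataclass
class _Block:
    name: str
    kind: str  # 'parametric' | 'smooth' | 'tensor' | 'random'
    sl: slice
    S: np.ndarray | None = None  # unscaled penalty, block-local
    basis: object = None  # SmoothBasis / (SmoothBasis, SmoothBasis) / levels
    lam: float = 1.0


@dataclass
class GammFit:
    """A fitted penalized binomial GAMM."""

    coef: np.ndarray
    blocks: list
    loglik: float
    edf_by_term: dict
    edf_total: float
    aic: float
    laml: float
    converged: bool
    n_irls: int
    separation_flag: bool
    param_names: list
    smooths: tuple
    factors: tuple
    factor_levels: dict
    spatial: bool
    random: str | None
    train_range: dict
    y_mean: float

    @property
    def random_intercept_sd(self) -> float | None:
        for b in self.blocks:
            if b.kind == "random":
                return 1.0 / np.sqrt(b.lam)
        return None

    def lambda_by_term(self) -> dict:
        return {b.name: b.lam for b in self.blocks if b.S is not None}

    def linear_predictor(self, data: pd.DataFrame, with_random: bool = False):
        X, flags = _design_for(self, data, allow_new=True)
        eta = X @ self.coef
        if not with_random:
            pass  # random columns are zeroed inside _design_for for new data
        return eta, flags

    def predict(self, data: pd.DataFrame):
        """Probabilities at new data (random effect at its population mean 0).

        Returns ``(probs, extrapolation_flags)``; covariates outside the
        training range are clipped to it and flagged.
        """
        eta, flags = self.linear_predictor(data)
        return expit(eta), flags

    def term_effect(self, data: pd.DataFrame, term: str) -> np.ndarray:
        """Contribution of one smooth term to the linear predictor."""
        X, _ = _design_for(self, data, allow_new=True)
        for b in self.blocks:
            if b.name == term:
                return X[:, b.sl] @ self.coef[b.sl]
        raise KeyError(term)


def _factor_design(data, factors, levels=None):
    cols, names = [], []
    levels = levels or {}
    out_levels = {}
    for f in factors:
        lv = levels.get(f) or sorted(map(str, data[f].astype(str).unique()))
        out_levels[f] = lv
        for l in lv[1:]:  # treatment coding, first level is reference
            cols.append((data[f].astype(str) == l).to_numpy(dtype=float))
            names.append(f"{f}[{l}]")
    return cols, names, out_levels


def _build_design(
    data: pd.DataFrame,
    smooths: tuple,
    factors: tuple,
    spatial: bool,
    random: str | None,
    n_basis: int,
    tensor_k: int,
):
    n = len(data)
    blocks: list[_Block] = []
    cols = [np.ones(n)]
    p0 = 1
    fcols, fnames, flevels = _factor_design(data, factors)
    cols += fcols
    p0 += len(fcols)
    blocks.append(_Block("parametric", "parametric", slice(0, p0)))
    param_names = ["(Intercept)"] + fnames

    pos = p0
    for s in smooths:
        sb = SmoothBasis.from_data(data[s].to_numpy(), n_basis=n_basis)
        B = sb.design(data[s].to_numpy())
        B = B - B.mean(axis=0, keepdims=True)  # center: intercept carries the mean
        cols.append(B)
        blocks.append(_Block(s, "smooth", slice(pos, pos + B.shape[1]), sb.penalty(), sb))
        pos += B.shape[1]

    if spatial:
        sbx = SmoothBasis.from_data(data["x_km"].to_numpy(), n_basis=tensor_k)
        sby = SmoothBasis.from_data(data["y_km"].to_numpy(), n_basis=tensor_k)
        Bx = sbx.design(data["x_km"].to_numpy())
        By = sby.design(data["y_km"].to_numpy())
        T = (Bx[:, :, None] * By[:, None, :]).reshape(n, -1)
        T = T - T.mean(axis=0, keepdims=True)
        px, py = Bx.shape[1], By.shape[1]
        S = np.kron(sbx.penalty(), np.eye(py)) + np.kron(np.eye(px), sby.penalty())
        cols.append(T)
        blocks.append(_Block("spatial", "tensor", slice(pos, pos + px * py), S, (sbx, sby)))
        pos += px * py

    re_levels = None
    if random is not None:
        re_levels = sorted(map(str, data[random].astype(str).unique()))
        Z = np.zeros((n, len(re_levels)))
        idx = pd.Categorical(data[random].astype(str), categories=re_levels).codes
        Z[np.arange(n), idx] = 1.0
        cols.append(Z)
        blocks.append(
            _Block(random, "random", slice(pos, pos + len(re_levels)), np.eye(len(re_levels)), re_levels)
        )
        pos += len(re_levels)

    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return X, blocks, flevels, param_names


def _design_for(fit: GammFit, data: pd.DataFrame, allow_new: bool):
    """Rebuild the design matrix for new data using the stored bases."""
    n = len(data)
    p = len(fit.coef)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    flags = np.zeros(n, dtype=bool)
    # parametric factor columns
    fcols, _, _ = _factor_design(data, fit.factors, fit.factor_levels)
    for j, c in enumerate(fcols, start=1):
        X[:, j] = c
    for b in fit.blocks:
        if b.kind == "smooth":
            x = data[b.name].to_numpy(dtype=float)
            lo, hi = fit.train_range[b.name]
            flags |= (x < lo) | (x > hi)
            B = b.basis.design(np.clip(x, lo, hi))
            X[:, b.sl] = B - fit.train_range[f"__mean__{b.name}"]
        elif b.kind == "tensor":
            sbx, sby = b.basis
            x = np.clip(data["x_km"].to_numpy(dtype=float), *fit.train_range["x_km"])
            y = np.clip(data["y_km"].to_numpy(dtype=float), *fit.train_range["y_km"])
            flags |= (data["x_km"].to_numpy() != x) | (data["y_km"].to_numpy() != y)
            T = (sbx.design(x)[:, :, None] * sby.design(y)[:, None, :]).reshape(n, -1)
            X[:, b.sl] = T - fit.train_range["__mean__spatial"]
        elif b.kind == "random":
            pass  # population-level prediction: random effect = 0
    return X, flags


def _pirls(X, y, blocks, lam, beta0=None, max_iter=100, tol=1e-8):
    """Penalized IRLS (Newton with step halving). Returns fit internals."""
    n, p = X.shape
    S = np.zeros((p, p))
    for b in blocks:
        if b.S is not None:
            S[b.sl, b.sl] += lam[b.name] * b.S
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def pll(bta, eta=None):
        if eta is None:
            eta = X @ bta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(bta @ S @ bta), ll

    f_old, ll = pll(beta)
    converged = False
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        g = X.T @ (y - mu) - S @ beta
        H = (X * w[:, None]).T @ X + S
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            f_new, ll_new = pll(cand)
            if f_new >= f_old - 1e-12:
                break
            step *= 0.5
        beta, f_gain = cand, f_new - f_old
        f_old, ll = f_new, ll_new
        if np.abs(g).max() < tol * max(1.0, abs(f_old)) or f_gain < 1e-10:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    XtWX = (X * w[:, None]).T @ X
    H = XtWX + S
    separation = bool(np.abs(eta).max() > 25.0)
    return {
        "beta": beta,
        "loglik": ll,
        "pen_loglik": f_old,
        "H": H,
        "XtWX": XtWX,
        "S": S,
        "converged": converged,
        "n_iter": it,
        "separation": separation,
    }


def _laml(res, blocks, lam):
    """Laplace approximate marginal likelihood (additive constants dropped)."""
    sign, logdetH = np.linalg.slogdet(res["H"])
    if sign <= 0:
        return -np.inf
    val = res["pen_loglik"] - 0.5 * logdetH
    for b in blocks:
        if b.S is not None:
            pj = b.sl.stop - b.sl.start
            val += 0.5 * pj * np.log(lam[b.name])
    return float(val)


def _edf(res, blocks):
    A = np.linalg.solve(res["H"], res["XtWX"])
    edf = {}
    for b in blocks:
        edf[b.name] = float(np.trace(A[b.sl, b.sl]))
    return edf


DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-2.0, 4.1, 0.5))
DEFAULT_RE_GRID = tuple(10.0 ** np.arange(-2.0, 4.1, 0.25))


def fit_binomial_gamm(
    data: pd.DataFrame,
    y: str = "y",
    smooths: tuple = (),
    factors: tuple = (),
    spatial: bool = False,
    random: str | None = None,
    n_basis: int = 10,
    tensor_k: int = 5,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    re_grid=DEFAULT_RE_GRID,
    sweeps: int = 2,
    fixed_lambda: dict | None = None,
    min_obs: int = 200,
) -> GammFit:
    """Fit the penalized binomial GAMM by P-IRLS with Laplace-ML smoothing.

    ``data`` must contain the 0/1 response ``y``, every smooth covariate,
    factor columns, projected ``x_km``/``y_km`` when ``spatial``, and the
    individual-id column named by ``random``. Smoothing parameters (one per
    smooth, one for the tensor, one for the random-intercept precision) are
    selected by coordinate descent over log-spaced grids, maximizing the
    Laplace approximate marginal likelihood; pass ``fixed_lambda`` to pin
    any of them. Raises for fewer than ``min_obs`` rows or, with a random
    term, fewer than 2 individuals.
    """
    if len(data) < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {len(data)}")
    if random is not None and data[random].nunique() < 2:
        raise ValueError("random-intercept model needs at least 2 individuals")
    yv = data[y].to_numpy(dtype=float)
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    X, blocks, flevels, param_names = _build_design(
        data, tuple(smooths), tuple(factors), spatial, random, n_basis, tensor_k
    )
    fixed_lambda = fixed_lambda or {}
    lam = {}
    for b in blocks:
        if b.S is None:
            continue
        lam[b.name] = float(fixed_lambda.get(b.name, 1.0))

    res = _pirls(X, yv, blocks, lam)
    beta = res["beta"]
    tunable = [b for b in blocks if b.S is not None and b.name not in fixed_lambda]
    for _ in range(sweeps):
        for b in tunable:
            grid = re_grid if b.kind == "random" else lambda_grid
            best = (None, None)
            for g in grid:
                trial = dict(lam)
                trial[b.name] = float(g)
                r = _pirls(X, yv, blocks, trial, beta0=beta)
                v = _laml(r, blocks, trial)
                if best[0] is None or v > best[0]:
                    best = (v, float(g), r)
            lam[b.name] = best[1]
            res = best[2]
            beta = res["beta"]
    # final polish at the selected smoothing parameters
    res = _pirls(X, yv, blocks, lam, beta0=beta, tol=1e-10)

    for b in blocks:
        if b.S is not None:
            b.lam = lam[b.name]
    edf = _edf(res, blocks)
    edf_total = float(sum(edf.values()))
    aic = -2.0 * res["loglik"] + 2.0 * edf_total

    train_range = {}
    for s in smooths:
        xv = data[s].to_numpy(dtype=float)
        train_range[s] = (float(xv.min()), float(xv.max()))
    for b in blocks:
        if b.kind == "smooth":
            B = b.basis.design(data[b.name].to_numpy())
            train_range[f"__mean__{b.name}"] = B.mean(axis=0)
        elif b.kind == "tensor":
            sbx, sby = b.basis
            T = (
                sbx.design(data["x_km"].to_numpy())[:, :, None]
                * sby.design(data["y_km"].to_numpy())[:, None, :]
            ).reshape(len(data), -1)
            train_range["__mean__spatial"] = T.mean(axis=0)
            train_range["x_km"] = (float(data["x_km"].min()), float(data["x_km"].max()))
            train_range["y_km"] = (float(data["y_km"].min()), float(data["y_km"].max()))

    if not res["converged"]:
        warnings.warn(f"P-IRLS did not converge in {res['n_iter']} iterations")
    if res["separation"]:
        warnings.warn("possible complete separation: |linear predictor| > 25")

    return GammFit(
        coef=res["beta"],
        blocks=blocks,
        loglik=float(res["loglik"]),
        edf_by_term=edf,
        edf_total=edf_total,
        aic=float(aic),
        laml=_laml(res, blocks, lam),
        converged=bool(res["converged"]),
        n_irls=int(res["n_iter"]),
        separation_flag=bool(res["separation"]),
        param_names=param_names,
        smooths=tuple(smooths),
        factors=tuple(factors),
        factor_levels=flevels,
        spatial=spatial,
        random=random,
        train_range=train_range,
        y_mean=float(yv.mean()),
    )


def predict_foraging(fit: GammFit, data: pd.DataFrame):
    """Back-transformed foraging probabilities with extrapolation flags."""
    return fit.predict(data)


def aic_dredge(
    data: pd.DataFrame,
    candidate_smooths: tuple,
    factors: tuple = (),
    include_spatial: bool = False,
    random: str | None = None,
    always_smooths: tuple = (),
    **fit_kwargs,
):
    """Exhaustive AIC ranking over subsets of candidate smooth terms.

    Factor terms (and ``always_smooths``) appear in every candidate model,
    mirroring a fixed-effects structure with an all-subsets dredge over the
    environmental smooths (and optionally the spatial smooth). Limited to 12
    candidates (2^12 models). Returns ``(table, best_fit)``; the table has
    one row per successfully fitted subset with logLik, edf, AIC and
    delta_aic, and ``table.attrs['ambiguous']`` is True when the runner-up
    is within 2 AIC units.
    """
    cands = list(candidate_smooths) + (["spatial"] if include_spatial else [])
    if len(cands) > 12:
        raise ValueError("more than 12 candidate terms: exhaustive dredge capped at 2^12")
    rows, fits = [], {}
    for r in range(len(cands) + 1):
        for subset in itertools.combinations(cands, r):
            sm = tuple(always_smooths) + tuple(s for s in subset if s != "spatial")
            sp = "spatial" in subset
            try:
                f = fit_binomial_gamm(
                    data,
                    smooths=sm,
                    factors=factors,
                    spatial=sp,
                    random=random,
                    **fit_kwargs,
                )
            except Exception as e:  # failed subset: recorded, skipped
                rows.append(
                    {"terms": "+".join(subset) or "(null)", "error": str(e)}
                )
                continue
            key = "+".join(subset) or "(null)"
            rows.append(
                {
                    "terms": key,
                    "logLik": f.loglik,
                    "edf": f.edf_total,
                    "AIC": f.aic,
                }
            )
            fits[key] = f
    tab = pd.DataFrame(rows)
    ok = tab[tab.get("error").isna()] if "error" in tab.columns else tab
    ok = ok.sort_values("AIC").reset_index(drop=True)
    ok["delta_aic"] = ok["AIC"] - ok["AIC"].iloc[0]
    ambiguous = len(ok) > 1 and float(ok["delta_aic"].iloc[1]) <= 2.0
    ok.attrs["ambiguous"] = ambiguous
    if ambiguous:
        warnings.warn("AIC selection ambiguous: runner-up within 2 AIC units")
    return ok, fits[ok["terms"].iloc[0]]
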