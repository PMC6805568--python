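"""Net squared displacement (NSD) and latent-state segmentation.

NSD is the squared great-circle distance between each average daily track
location and the first recorded location of the trip. Its time series is
segmented into three latent states with a Gaussian hidden Markov model on
square-root-transformed NSD: two low-variance "encamped" states (state 1 =
summer residency near the colony, state 2 = winter residency far away) and
one high-variance "transit" state (state 3). The maximum-likelihood HMM
with Viterbi decoding stands in for a Bayesian latent-state formulation:
only the decoded state sequence is consumed downstream, so posteriors and
credible intervals are not needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .geo import haversine_km, normalize_lon, unwrap_lon

__all__ = [
    "daily_mean_locations",
    "compute_nsd",
    "LatentStateModel",
    "fit_latent_states",
    "decode_states",
    "winter_range",
    "winter_env_pca",
]


def daily_mean_locations(track: pd.DataFrame) -> pd.DataFrame:
    """Per-UTC-day mean location of a (filtered) fix series.

    Longitude is unwrapped before averaging so days straddling the prime or
    antimeridian average on the short arc. Days without fixes are absent.
    Returns columns date, lon, lat (plus id if present).
    """
    t = pd.to_datetime(track["timestamp"])
    df = pd.DataFrame(
        {
            "date": t.dt.floor("D"),
            "lon_u": unwrap_lon(track["lon"].to_numpy()),
            "lat": track["lat"].to_numpy(dtype=float),
        }
    )
    g = df.groupby("date", as_index=False).mean()
    out = pd.DataFrame(
        {"date": g["date"], "lon": normalize_lon(g["lon_u"]), "lat": g["lat"]}
    )
    if "id" in track.columns and len(track):
        out.insert(0, "id", track["id"].iloc[0])
    return out


def compute_nsd(daily: pd.DataFrame) -> pd.DataFrame:
    """Attach nsd (km²) to a daily-location series: squared distance to day 1."""
    if len(daily) < 2:
        raise ValueError("need at least 2 daily locations")
    lon0, lat0 = daily["lon"].iloc[0], daily["lat"].iloc[0]
    d = haversine_km(lon0, lat0, daily["lon"].to_numpy(), daily["lat"].to_numpy())
    out = daily.copy()
    out["nsd"] = d**2
    return out


@dataclass
class LatentStateModel:
    """Fitted 3-state Gaussian HMM on transformed NSD."""

    means: np.ndarray  # per-state emission mean, transformed scale, relabeled
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    n_iterations: int
    loglik_history: np.ndarray
    seed: int
    transform: str = "sqrt"
    degenerate: bool = False
    state_order: np.ndarray = field(default_factory=lambda: np.arange(3))

    def _hmm(self) -> GaussianHMM:
        m = GaussianHMM(n_components=len(self.means), covariance_type="diag")
        m.means_ = self.means.reshape(-1, 1)
        m.covars_ = np.maximum(self.sds.reshape(-1, 1) ** 2, 1e-10)
        m.transmat_ = self.transmat
        m.startprob_ = self.startprob
        m.n_features = 1
        return m


def _transform_nsd(nsd, transform):
    nsd = np.asarray(nsd, dtype=float)
    if transform == "sqrt":
        return np.sqrt(np.maximum(nsd, 0.0))
    if transform == "log1p":
        return np.log1p(np.maximum(nsd, 0.0))
    raise ValueError(f"unknown transform {transform!r}")


def fit_latent_states(
    series: pd.DataFrame,
    n_states: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    transform: str = "sqrt",
    max_iter: int = 200,
) -> LatentStateModel:
    """Fit the latent-state model to one individual's NSD series.

    EM (Baum-Welch) with ``n_restarts`` random initializations; the best
    log-likelihood wins. States are relabeled so that of the two
    lowest-variance (encamped) states the one with the smaller emission
    mean is state 1 and the larger is state 2; the highest-variance state
    is state 3 (transit). A constant series triggers a flagged single-state
    fallback.
    """
    if len(series) < 20:
        raise ValueError("need at least 20 daily NSD values")
    y = _transform_nsd(series["nsd"].to_numpy(), transform).reshape(-1, 1)

    if np.ptp(y) < 1e-9:
        warnings.warn("constant NSD series: single-state degenerate fallback")
        return LatentStateModel(
            means=np.array([float(y[0, 0])]),
            sds=np.array([0.0]),
            transmat=np.ones((1, 1)),
            startprob=np.ones(1),
            log_likelihood=np.nan,
            n_iterations=0,
            loglik_history=np.array([]),
            seed=seed,
            transform=transform,
            degenerate=True,
            state_order=np.array([0]),
        )

    best = None
    for r in range(n_restarts):
        hmm = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=1e-4,
            random_state=seed + r,
            init_params="stmc",
            min_covar=1e-5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                hmm.fit(y)
            except ValueError:
                continue
        ll = float(hmm.monitor_.history[-1])
        if best is None or ll > best[0]:
            best = (ll, hmm)
    if best is None:
        raise RuntimeError("all EM restarts failed")
    ll, hmm = best
    if not hmm.monitor_.converged:
        warnings.warn("EM did not converge within max_iter; best-so-far kept")

    means = hmm.means_.ravel()
    sds = np.sqrt(hmm.covars_.ravel())
    # transit = highest emission variance; encamped states ordered by mean
    transit = int(np.argmax(sds))
    encamped = [i for i in range(n_states) if i != transit]
    encamped.sort(key=lambda i: means[i])
    order = np.array(encamped + [transit])  # original index of new state 1..3
    perm = order
    return LatentStateModel(
        means=means[perm],
        sds=sds[perm],
        transmat=hmm.transmat_[np.ix_(perm, perm)],
        startprob=hmm.startprob_[perm],
        log_likelihood=ll,
        n_iterations=len(hmm.monitor_.history),
        loglik_history=np.asarray(hmm.monitor_.history, dtype=float),
        seed=seed,
        transform=transform,
        state_order=perm,
    )


def decode_states(model: LatentStateModel, series: pd.DataFrame) -> pd.DataFrame:
    """Attach the Viterbi most-likely state path (1..3) to an NSD series."""
    out = series.copy()
    if model.degenerate:
        out["state"] = 1
        return out
    y = _transform_nsd(series["nsd"].to_numpy(), model.transform).reshape(-1, 1)
    path = model._hmm().predict(y)
    out["state"] = path + 1
    return out


def state_posteriors(model: LatentStateModel, series: pd.DataFrame) -> np.ndarray:
    """Forward-backward posterior state probabilities (rows sum to 1)."""
    y = _transform_nsd(series["nsd"].to_numpy(), model.transform).reshape(-1, 1)
    return model._hmm().predict_proba(y)


def winter_range(series_set: pd.DataFrame, cell_deg: float = 1.0) -> pd.DataFrame:
    """Bin all state-2 daily locations into cells; count days per cell.

    ``series_set``: decoded NSD series (any number of individuals) with
    columns lon, lat, state. Returns columns lon_bin, lat_bin (cell lower
    edges, degrees) and days. Empty if no state-2 days (with a warning).
    """
    s2 = series_set[series_set["state"] == 2]
    if len(s2) == 0:
        warnings.warn("no state-2 days: empty winter-range grid")
        return pd.DataFrame(columns=["lon_bin", "lat_bin", "days"])
    lon_bin = np.floor(normalize_lon(s2["lon"].to_numpy()) / cell_deg) * cell_deg
    lat_bin = np.floor(s2["lat"].to_numpy() / cell_deg) * cell_deg
    g = (
        pd.DataFrame({"lon_bin": lon_bin, "lat_bin": lat_bin})
        .groupby(["lon_bin", "lat_bin"], as_index=False)
        .size()
        .rename(columns={"size": "days"})
    )
    return g


def winter_env_pca(env_matrix: pd.DataFrame):
    """Column-standardized PCA (SVD) of environmental values at state-2 locations.

    Constant columns are dropped with a warning. Returns
    ``(loadings, scores, variance_fraction)``; variance fractions sum to 1.
    Loadings columns are principal components; rows correspond to the
    retained variables (DataFrame index preserves their names).
    """
    X = env_matrix.dropna()
    if len(X) < 2:
        raise ValueError("need at least 2 complete rows for PCA")
    sd = X.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant columns: {list(sd.index[~keep])}")
        X = X.loc[:, keep]
    Z = (X - X.mean()) / X.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = s**2 / np.sum(s**2)
    loadings = pd.DataFrame(
        Vt.T, index=X.columns, columns=[f"PC{i+1}" for i in range(len(s))]
    )
    scores = U * s
    return loadings, scores, var
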