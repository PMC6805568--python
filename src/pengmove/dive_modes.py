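"""Behavioral dive modes: hourly aggregation, clustering, labeling.

Hourly records combine four variables — mean maximum dive depth (m), mean
dive duration (s), mean post-dive surface interval (s) and mean travel
speed (km/h, from distances between consecutive dive locations divided by
the time between dive initiations). Records are standardized and clustered
by agglomerative hierarchical clustering with Manhattan (L1) distance and
UPGMA (unweighted average) linkage, cut at k = 3. The fastest-travel
cluster is labeled 'traveling'; the rest 'foraging'. Clustering runs
separately per stage (juveniles vs non-breeders).

Standardization before the L1 distance is deliberate: the variables mix
meters, seconds and km/h, and unscaled distances would be dominated by
dive depth. A raw-scale option is retained for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .geo import haversine_km

VARIABLES = ["depth_m", "duration_s", "surface_s", "speed_kmh"]

__all__ = [
    "VARIABLES",
    "assign_dive_locations",
    "dive_travel_speed",
    "hourly_aggregate",
    "cluster_hourly",
    "ClusterSummary",
    "label_modes",
    "mode_time_series",
]


def assign_dive_locations(
    dives: pd.DataFrame, track: pd.DataFrame, max_gap_min: float = 90.0
) -> pd.DataFrame:
    """Attach the nearest-in-time filtered fix to each dive.

    Dives farther than ``max_gap_min`` minutes from any fix are dropped
    (count retained in the ``attrs`` of the result).
    """
    t_fix = pd.to_datetime(track["timestamp"]).to_numpy()
    order = np.argsort(t_fix)
    t_fix = t_fix[order]
    lon = track["lon"].to_numpy()[order]
    lat = track["lat"].to_numpy()[order]
    t_dive = pd.to_datetime(dives["start"]).to_numpy()
    pos = np.searchsorted(t_fix, t_dive)
    pos = np.clip(pos, 1, len(t_fix) - 1)
    left, right = pos - 1, pos
    d_left = np.abs((t_dive - t_fix[left]).astype("timedelta64[s]").astype(float))
    d_right = np.abs((t_fix[right] - t_dive).astype("timedelta64[s]").astype(float))
    nearest = np.where(d_left <= d_right, left, right)
    gap_s = np.minimum(d_left, d_right)
    out = dives.copy()
    out["lon"] = lon[nearest]
    out["lat"] = lat[nearest]
    ok = gap_s <= max_gap_min * 60.0
    dropped = int((~ok).sum())
    out = out[ok].reset_index(drop=True)
    out.attrs["n_dropped_no_fix"] = dropped
    return out


def dive_travel_speed(
    dives_located: pd.DataFrame, max_speed_kmh: float | None = 14.0
) -> pd.DataFrame:
    """Speed (km/h) between consecutive dives of one individual and day.

    Distance between consecutive dive locations divided by the difference of
    dive initiation times (which therefore includes dive duration). The
    first dive of each recording day has no predecessor; the single dive of
    a day yields no defined speed and its record is dropped. Pairs implying
    speed above ``max_speed_kmh`` (location error between closely spaced
    dives mapped to different fixes) are dropped as physically impossible,
    the same ceiling the track filter uses; pass None to keep everything.
    """
    df = dives_located.sort_values("start").reset_index(drop=True)
    t = pd.to_datetime(df["start"])
    day = t.dt.floor("D")
    parts = []
    for (_, _), sub in df.groupby([df["id"], day], sort=True):
        if len(sub) < 2:
            continue
        tt = pd.to_datetime(sub["start"]).astype("int64").to_numpy() / 3.6e12
        d = haversine_km(
            sub["lon"].to_numpy()[:-1],
            sub["lat"].to_numpy()[:-1],
            sub["lon"].to_numpy()[1:],
            sub["lat"].to_numpy()[1:],
        )
        dt = np.diff(tt)
        sp = np.full(len(sub), np.nan)
        ok = dt > 0
        sp[1:][ok] = d[ok] / dt[ok]
        sub = sub.copy()
        sub["speed_kmh"] = sp
        sub = sub.iloc[1:]  # first dive of the day: speed undefined
        sub = sub[np.isfinite(sub["speed_kmh"])]
        if max_speed_kmh is not None:
            sub = sub[sub["speed_kmh"] <= max_speed_kmh]
        parts.append(sub)
    if not parts:
        return df.iloc[0:0].assign(speed_kmh=np.nan)
    return pd.concat(parts, ignore_index=True)


def hourly_aggregate(dives_with_speed: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic hourly means per individual; hours with zero dives absent.

    Input needs id, start, max_depth_m, duration_s, surface_s, speed_kmh
    (plus optional truth columns which are carried through as modal values).
    """
    df = dives_with_speed.copy()
    df["hour"] = pd.to_datetime(df["start"]).dt.floor("h")
    agg = {
        "max_depth_m": "mean",
        "duration_s": "mean",
        "surface_s": "mean",
        "speed_kmh": "mean",
    }
    for c in ("lon", "lat"):
        if c in df.columns:
            agg[c] = "mean"
    extra = {}
    for c in ("regime", "cluster"):
        if c in df.columns:
            extra[c] = lambda s: s.mode().iloc[0]
    g = df.groupby(["id", "hour"], as_index=False).agg(agg | extra | {"start": "size"})
    g = g.rename(
        columns={
            "max_depth_m": "depth_m",
            "duration_s": "duration_s",
            "surface_s": "surface_s",
            "start": "n_dives",
        }
    )
    if "stage" in dives_with_speed.columns:
        stage_map = dives_with_speed.groupby("id")["stage"].first()
        g["stage"] = g["id"].map(stage_map)
    return g


def _consolidated_cut(Z: np.ndarray, tree: np.ndarray, k: int, sub=None) -> np.ndarray:
    """Cut the tree at several depths; k-means-consolidate; keep best.

    Each candidate initialization takes the centroids of the ``k`` largest
    clusters of a cut; candidates whose smallest seed cluster holds < 3
    records are skipped. Lowest k-means inertia wins (ties keep the
    shallowest cut, so the result is deterministic).
    """
    from sklearn.cluster import KMeans

    Zt = Z if sub is None else Z[sub]
    n = len(Zt)
    best = None
    for kk in range(k, min(k + 21, n), 4):
        lab = fcluster(tree, t=kk, criterion="maxclust")
        sizes = np.bincount(lab)[1:]
        big = np.argsort(-sizes, kind="stable")[:k] + 1
        if len(big) < k or sizes[big - 1].min() < 3:
            continue
        cent = np.vstack([Zt[lab == c].mean(axis=0) for c in big])
        km = KMeans(n_clusters=k, init=cent, n_init=1, max_iter=100).fit(Z)
        if best is None or km.inertia_ < best[0] - 1e-9:
            best = (km.inertia_, km.labels_ + 1)
    if best is None:  # tiny inputs: fall back to the plain cut
        return fcluster(tree, t=k, criterion="maxclust")
    return best[1]


def standardize(X: np.ndarray):
    """Z-score columns; returns (Z, mean, sd). Constant columns keep sd=1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def cluster_hourly(
    records: pd.DataFrame,
    k: int = 3,
    scale: bool = True,
    consolidate: bool = True,
    max_tree_n: int = 6000,
):
    """UPGMA / Manhattan clustering of hourly records into ``k`` clusters.

    A hierarchical tree is built with Manhattan (L1) distance on the
    standardized variables and unweighted-average (UPGMA) linkage. With
    ``consolidate=False`` the tree is simply cut at ``k`` clusters. The
    default adds the k-means consolidation pass of the HCPC workflow this
    stage mirrors: average linkage tends to spend cluster slots on outlier
    singletons, so the tree is cut at several depths, the centroids of the
    ``k`` largest clusters at each depth seed a k-means refinement, and the
    solution with the lowest within-cluster dispersion is kept. The whole
    procedure is deterministic for a fixed input order.

    Returns ``(labels, linkage_matrix, summary)`` where labels are 1..k in
    order of first appearance in the input, and summary is a
    :class:`ClusterSummary`. Requires at least ``k`` records.
    """
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    X = records[VARIABLES].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering variables")
    Z = standardize(X)[0] if scale else X
    # the O(n^2) tree is built on an evenly spaced subsample when records
    # are plentiful; consolidation then assigns every record
    if len(Z) > max_tree_n:
        if not consolidate:
            raise ValueError(
                f"{len(Z)} records exceed max_tree_n={max_tree_n}; "
                "plain tree cut needs consolidate=True or a larger cap"
            )
        sub = np.linspace(0, len(Z) - 1, max_tree_n).round().astype(int)
    else:
        sub = np.arange(len(Z))
    D = pdist(Z[sub], metric="cityblock")
    tree = linkage(D, method="average")
    if consolidate:
        raw = _consolidated_cut(Z, tree, k, sub)
    else:
        raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel deterministically by order of first appearance
    relabel = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    summary = summarize_clusters(records, labels)
    return labels, tree, summary


@dataclass
class ClusterSummary:
    """Per-cluster mean±SD of the four variables, time share and mode label."""

    table: pd.DataFrame  # index: cluster id; columns: <var>_mean, <var>_sd, proportion
    modes: dict | None = None  # cluster id -> 'traveling' | 'foraging'
    warnings: list = None

    def to_dict(self) -> dict:
        return {
            "table": self.table.reset_index().to_dict(orient="records"),
            "modes": self.modes,
            "warnings": self.warnings or [],
        }


def summarize_clusters(records: pd.DataFrame, labels) -> ClusterSummary:
    df = records.copy()
    df["_cluster"] = labels
    rows = {}
    for c, sub in df.groupby("_cluster"):
        row = {}
        for v in VARIABLES:
            row[f"{v}_mean"] = sub[v].mean()
            row[f"{v}_sd"] = sub[v].std(ddof=1)
        row["proportion"] = len(sub) / len(df)
        rows[c] = row
    return ClusterSummary(table=pd.DataFrame(rows).T.rename_axis("cluster"))


def label_modes(summary: ClusterSummary) -> ClusterSummary:
    """Assign 'traveling' to the fastest cluster, 'foraging' to the rest.

    Validation: the traveling cluster must not also have the deepest mean
    depth; a violation (or a speed tie) is flagged in ``summary.warnings``
    rather than silently accepted.
    """
    t = summary.table
    warns = []
    speeds = t["speed_kmh_mean"]
    top = speeds.idxmax()
    if (speeds == speeds.max()).sum() > 1:
        warns.append("speed tie between clusters: traveling label ambiguous")
    modes = {c: ("traveling" if c == top else "foraging") for c in t.index}
    if t.loc[top, "depth_m_mean"] >= t["depth_m_mean"].max():
        warns.append("traveling cluster has the deepest mean depth: review labels")
    summary.modes = modes
    summary.warnings = warns
    for w in warns:
        warnings.warn(w)
    return summary


def mode_time_series(records: pd.DataFrame, departure: dict | None = None) -> pd.DataFrame:
    """Weekly traveling/foraging time proportions per stage.

    Week index counts from each individual's departure (its first record by
    default, or explicit per-id departure timestamps). Proportions within a
    stage-week sum to 1.
    """
    df = records.copy()
    if "mode" not in df.columns:
        raise ValueError("records must carry a 'mode' column (label_modes output)")
    t = pd.to_datetime(df["hour"])
    if departure is None:
        dep = df.groupby("id")["hour"].transform("min")
    else:
        dep = df["id"].map(departure)
    week = ((t - pd.to_datetime(dep)).dt.total_seconds() // (7 * 86400)).astype(int)
    df["week"] = week
    if "stage" not in df.columns:
        df["stage"] = "all"
    g = df.groupby(["stage", "week", "mode"], as_index=False).size()
    tot = g.groupby(["stage", "week"])["size"].transform("sum")
    g["proportion"] = g["size"] / tot
    return g
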