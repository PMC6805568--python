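"""Maximum-speed filtering of Argos location series.

Satellite-derived fixes carry occasional multi-hundred-km errors. The filter
removes fixes whose implied travel speed is physically impossible for the
animal (default ceiling 14 km/h for king penguins), using an iterative
McConnell-style scheme: each interior fix is scored by the root-mean-square
of the speeds to up to two previous and two subsequent retained fixes, and
the worst offender is removed until no interior fix is implicated in a
speed violation. Endpoints are never removed — a terminal fix has one-sided
evidence only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km

DEFAULT_VMAX_KMH = 14.0

__all__ = ["DEFAULT_VMAX_KMH", "FilterReport", "travel_speed_kmh", "speed_filter", "filter_dataset"]


@dataclass
class FilterReport:
    """Bookkeeping for a speed-filter pass over one or more tracks."""

    n_input: int
    n_removed: int
    removed_indices: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "removed_fraction": self.removed_fraction,
            "removed_indices": list(map(int, self.removed_indices)),
            "notes": list(self.notes),
        }


def travel_speed_kmh(a, b) -> float:
    """Great-circle speed in km/h between two fixes.

    Each fix is a mapping/namespace with ``lon``, ``lat`` and ``timestamp``.
    Raises ValueError unless ``b`` is strictly later than ``a``.
    """

    def get(f, k):
        return f[k] if isinstance(f, (dict, pd.Series)) else getattr(f, k)

    t0, t1 = pd.Timestamp(get(a, "timestamp")), pd.Timestamp(get(b, "timestamp"))
    dt_h = (t1 - t0).total_seconds() / 3600.0
    if dt_h <= 0:
        raise ValueError("fixes must be in strictly increasing time order")
    d = float(haversine_km(get(a, "lon"), get(a, "lat"), get(b, "lon"), get(b, "lat")))
    return d / dt_h


def _pair_speeds(lon, lat, t_h, keep):
    """Speeds between consecutive retained fixes; len == n_kept - 1."""
    idx = np.flatnonzero(keep)
    d = haversine_km(lon[idx[:-1]], lat[idx[:-1]], lon[idx[1:]], lat[idx[1:]])
    return idx, d / np.diff(t_h[idx])


def _rms_scores(lon, lat, t_h, keep):
    """Per-retained-fix RMS of speeds to up to 2 previous / 2 next retained fixes."""
    idx = np.flatnonzero(keep)
    n = len(idx)
    ssq = np.zeros(n)
    cnt = np.zeros(n)
    for off in (-2, -1, 1, 2):
        if n <= abs(off):
            continue
        j = np.arange(max(0, -off), n - max(0, off))
        a, b = idx[j], idx[j + off]
        dt = np.abs(t_h[b] - t_h[a])
        ok = dt > 0
        sp2 = np.zeros(len(j))
        sp2[ok] = (haversine_km(lon[a[ok]], lat[a[ok]], lon[b[ok]], lat[b[ok]]) / dt[ok]) ** 2
        ssq[j] += np.where(ok, sp2, 0.0)
        cnt[j] += ok
    scores = np.sqrt(ssq / np.maximum(cnt, 1.0))
    return idx, scores


def speed_filter(track: pd.DataFrame, vmax: float = DEFAULT_VMAX_KMH):
    """Iteratively remove fixes implying travel faster than ``vmax`` km/h.

    Returns ``(filtered_track, FilterReport)``. The retained series satisfies
    speed <= vmax between every consecutive pair, except pairs involving an
    endpoint (endpoints are exempt and any terminal violation is noted in the
    report). Ties in the RMS score are broken toward the earlier fix, so the
    procedure is deterministic. Tracks with fewer than 3 fixes pass through
    unchanged with a warning note.
    """
    track = track.reset_index(drop=True)
    n = len(track)
    report = FilterReport(n_input=n, n_removed=0)
    if n < 3:
        msg = "track shorter than 3 fixes: speed filter skipped"
        warnings.warn(msg)
        report.notes.append(msg)
        return track, report

    t = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 3.6e12  # hours
    if not (np.diff(t) > 0).all():
        raise ValueError("timestamps must be strictly increasing within a track")
    lon = track["lon"].to_numpy(dtype=float)
    lat = track["lat"].to_numpy(dtype=float)
    keep = np.ones(n, dtype=bool)

    while True:
        idx, speeds = _pair_speeds(lon, lat, t, keep)
        bad_pairs = np.flatnonzero(speeds > vmax)
        # violations are actionable only if an interior fix is involved
        interior_bad = [
            k
            for k in bad_pairs
            if not (idx[k] == idx[0] and idx[k + 1] == idx[-1])
        ]
        if not len(interior_bad):
            break
        ridx, scores = _rms_scores(lon, lat, t, keep)
        cand = np.ones(len(ridx), dtype=bool)
        cand[0] = cand[-1] = False  # endpoints exempt
        over = cand & (scores > vmax)
        if over.any():
            pool = np.flatnonzero(over)
        else:
            # violation persists but no RMS exceeds vmax: drop the interior
            # member of the worst pair with the larger RMS score
            k = int(bad_pairs[np.argmax(speeds[bad_pairs])])
            pos = {int(i): j for j, i in enumerate(ridx)}
            members = [pos[int(idx[k])], pos[int(idx[k + 1])]]
            members = [m for m in members if 0 < m < len(ridx) - 1]
            if not members:
                break
            pool = np.array(members)
        worst = pool[np.argmax(scores[pool])]
        # argmax returns the first (earliest) maximum: deterministic tie-break
        keep[ridx[worst]] = False
        report.removed_indices.append(int(ridx[worst]))
        report.n_removed += 1

    # reinsertion pass: a clean fix sandwiched between spikes can transiently
    # carry the worst RMS; put back any removed fix that is compliant with
    # its retained neighbors once the true spikes are gone
    changed = True
    while changed:
        changed = False
        for i in sorted(report.removed_indices):
            kept = np.flatnonzero(keep)
            prev_ = kept[kept < i]
            next_ = kept[kept > i]
            ok = True
            if len(prev_):
                p = prev_[-1]
                ok &= float(haversine_km(lon[p], lat[p], lon[i], lat[i])) / (t[i] - t[p]) <= vmax
            if ok and len(next_):
                nx = next_[0]
                ok &= float(haversine_km(lon[i], lat[i], lon[nx], lat[nx])) / (t[nx] - t[i]) <= vmax
            if ok:
                keep[i] = True
                report.removed_indices.remove(i)
                report.n_removed -= 1
                changed = True

    _, speeds = _pair_speeds(lon, lat, t, keep)
    if len(speeds) and (speeds > vmax).any():
        report.notes.append("terminal speed violation retained (endpoints exempt)")
    report.removed_indices.sort()
    return track[keep].reset_index(drop=True), report


def filter_dataset(tracks: pd.DataFrame, vmax: float = DEFAULT_VMAX_KMH):
    """Apply :func:`speed_filter` per individual; aggregate the reports.

    ``tracks`` holds all individuals with an ``id`` column. Returns the
    concatenated filtered tracks and a pooled FilterReport (indices are
    positions within the input frame).
    """
    if len(tracks) == 0:
        return tracks.copy(), FilterReport(n_input=0, n_removed=0)
    parts = []
    agg = FilterReport(n_input=len(tracks), n_removed=0)
    for _, sub in tracks.groupby("id", sort=True):
        orig_pos = sub.index.to_numpy()
        filt, rep = speed_filter(sub, vmax=vmax)
        parts.append(filt)
        agg.n_removed += rep.n_removed
        agg.removed_indices.extend(int(orig_pos[i]) for i in rep.removed_indices)
        agg.notes.extend(rep.notes)
    agg.removed_indices.sort()
    out = pd.concat(parts, ignore_index=True)
    return out, agg
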