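"""First-passage time, characteristic-scale selection, ARS extraction.

First-passage time (FPT) at a path point is the time the animal takes to
traverse a circle of radius r centered on that point: the interval between
the first crossing of the circle scanning backward along the path and the
first crossing scanning forward.  The variance of log(FPT) across a bird's
points peaks at the spatial scale of area-restricted search (ARS), and
points in the upper tail of FPT at that scale are the putative foraging
locations.

Crossings are found exactly: on a piecewise-linear path the distance to a
fixed center is convex within each segment, so the first vertex beyond
radius r identifies the crossing segment, and the crossing position/time
solve a scalar quadratic with linear time interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import Trip

log = logging.getLogger(__name__)

__all__ = [
    "FPTProfile",
    "default_radii",
    "fpt_matrix",
    "first_passage_time",
    "scale_profile",
    "select_scale",
    "extract_ars",
]


def default_radii() -> np.ndarray:
    """The standard scan grid: 100–5000 m at a 100 m interval (50 radii)."""
    return np.arange(100.0, 5000.0 + 1, 100.0)


@dataclass
class FPTProfile:
    """Per-bird variance-of-log-FPT profile over the radius grid."""

    bird_id: str
    radii: np.ndarray
    var_log_fpt: np.ndarray  # NaN where < 2 defined FPT values
    n_defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bird_id": self.bird_id, "radius_m": self.radii,
                             "var_log_fpt": self.var_log_fpt, "n": self.n_defined})


def _crossing_time(P, t, centers, seg_end, r, backward: bool) -> np.ndarray:
    """Exact circle-crossing times for a batch of centers.

    ``seg_end`` gives, per center, the first vertex beyond radius r in the
    scan direction; the crossing lies in the segment between that vertex
    and its predecessor (in scan order).
    """
    if backward:
        i0, i1 = seg_end, seg_end + 1  # segment j -> j+1, entered from j+1 side
    else:
        i0, i1 = seg_end - 1, seg_end
    A = P[i1] - P[i0]
    B = P[i0] - P[centers]
    a = np.einsum("ij,ij->i", A, A)
    b = 2.0 * np.einsum("ij,ij->i", A, B)
    c = np.einsum("ij,ij->i", B, B) - r * r
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    sq = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        # forward scan: distance rises through r -> larger root;
        # backward scan (read along the path): falls through r -> smaller root
        u = (-b - sq) / (2 * a) if backward else (-b + sq) / (2 * a)
    u = np.where(a < 1e-30, 0.0, np.clip(u, 0.0, 1.0))
    return t[i0] + u * (t[i1] - t[i0])


def fpt_matrix(trip: Trip, radii: np.ndarray) -> np.ndarray:
    """FPT (seconds) for every path point × radius; NaN where undefined.

    A point's FPT at radius r is undefined when the path fails to exit the
    circle in either direction (typically near trip ends at large radii).
    """
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = len(trip)
    P = np.column_stack([trip.x, trip.y])
    t = np.asarray(trip.t, float)
    out = np.full((n, len(radii)), np.nan)
    if n < 2:
        return out
    D = cdist(P, P)
    idx = np.arange(n)
    upper = idx[None, :] > idx[:, None]
    for k, r in enumerate(radii):
        M = D > r
        Mf = M & upper
        fwd = Mf.argmax(axis=1)
        has_f = Mf[idx, fwd]
        Mb = M & ~upper & (idx[None, :] < idx[:, None])
        rev = Mb[:, ::-1].argmax(axis=1)
        bwd = n - 1 - rev
        has_b = Mb[idx, bwd]
        ok = has_f & has_b
        if not ok.any():
            continue
        c = idx[ok]
        tf = _crossing_time(P, t, c, fwd[ok], r, backward=False)
        tb = _crossing_time(P, t, c, bwd[ok], r, backward=True)
        out[c, k] = tf - tb
    return out


def first_passage_time(trip: Trip, radius: float) -> np.ndarray:
    """Per-point FPT at a single radius (NaN = undefined)."""
    return fpt_matrix(trip, np.array([float(radius)]))[:, 0]


def scale_profile(trips: list[Trip], radii: np.ndarray | None = None) -> list[FPTProfile]:
    """Variance of log(FPT) per radius, pooled over each bird's trip points."""
    if radii is None:
        radii = default_radii()
    radii = np.asarray(radii, float)
    by_bird: dict[str, list[np.ndarray]] = {}
    for tr in trips:
        by_bird.setdefault(tr.bird_id, []).append(fpt_matrix(tr, radii))
    profiles = []
    for bird in sorted(by_bird):
        F = np.vstack(by_bird[bird])
        with np.errstate(invalid="ignore"):
            L = np.log(F)
        n_def = np.sum(np.isfinite(L), axis=0)
        var = np.full(len(radii), np.nan)
        for k in range(len(radii)):
            if n_def[k] >= 2:
                var[k] = np.var(L[np.isfinite(L[:, k]), k], ddof=1)
        profiles.append(FPTProfile(bird, radii.copy(), var, n_def))
    return profiles


def select_scale(profiles: list[FPTProfile], rule: str = "mean_profile") -> float:
    """Choose the common ARS scale from per-bird variance profiles.

    ``mean_profile`` (default): average var log(FPT) across birds at each
    radius (ignoring missing) and return the radius of the peak mean, ties
    going to the smallest radius.  ``per_bird_max``: take each bird's own
    peak radius and return the largest of those.
    """
    if not profiles:
        raise ValueError("no profiles")
    radii = profiles[0].radii
    V = np.vstack([p.var_log_fpt for p in profiles])
    if not np.isfinite(V).any():
        raise ValueError("no radius has a defined variance for any bird")
    if rule == "mean_profile":
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(V, axis=0)
        return float(radii[np.nanargmax(mean)])
    if rule == "per_bird_max":
        peaks = [p.radii[np.nanargmax(p.var_log_fpt)] for p in profiles
                 if np.isfinite(p.var_log_fpt).any()]
        return float(max(peaks))
    raise ValueError(f"unknown rule {rule!r}")


def extract_ars(trips: list[Trip], scale: float, percentile: float = 90.0,
                reference: str = "bird") -> pd.DataFrame:
    """Foraging (ARS) points: upper-percentile FPT at the selected scale.

    The percentile threshold (linear-interpolation quantile) is computed
    over a reference FPT distribution — per bird by default, per trip or
    pooled over all birds via ``reference``.  A reference set with fewer
    than 10 defined values falls back to the pooled all-bird distribution.
    Returns one row per retained point with contiguous runs per trip
    labelled ``run_id`` for trip-level averaging downstream.
    """
    if reference not in ("bird", "trip", "pooled"):
        raise ValueError(f"unknown reference {reference!r}")
    per_trip = [(tr, first_passage_time(tr, scale)) for tr in trips]
    pooled = np.concatenate([f[np.isfinite(f)] for _, f in per_trip]) if per_trip else np.array([])

    def threshold(values: np.ndarray) -> float:
        vals = values[np.isfinite(values)]
        if len(vals) < 10:
            log.info("reference set has %d defined FPT values; falling back "
                     "to pooled distribution", len(vals))
            vals = pooled
        if len(vals) == 0:
            return np.inf
        return float(np.percentile(vals, percentile))

    bird_thr: dict[str, float] = {}
    if reference == "bird":
        by_bird: dict[str, list[np.ndarray]] = {}
        for tr, f in per_trip:
            by_bird.setdefault(tr.bird_id, []).append(f)
        bird_thr = {b: threshold(np.concatenate(fs)) for b, fs in by_bird.items()}
    pooled_thr = threshold(pooled) if reference == "pooled" else None

    rows = []
    for tr, f in per_trip:
        if reference == "trip":
            thr = threshold(f)
        elif reference == "bird":
            thr = bird_thr[tr.bird_id]
        else:
            thr = pooled_thr
        keep = np.isfinite(f) & (f >= thr)
        if not keep.any():
            continue
        ki = np.flatnonzero(keep)
        run = np.concatenate([[0], np.cumsum(np.diff(ki) > 1)])
        for r_id, i in zip(run, ki):
            rows.append((tr.bird_id, tr.trip_id, tr.year, tr.day,
                         int(r_id), tr.t[i], tr.x[i], tr.y[i], f[i]))
    return pd.DataFrame(rows, columns=["bird_id", "trip_id", "year", "day",
                                       "run_id", "t", "x", "y", "fpt_s"])
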