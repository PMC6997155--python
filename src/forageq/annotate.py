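"""Space-time environmental annotation, null points, trip-level quality.

Points are annotated with each environmental variable by inverse-distance
weighting (IDW) over the k nearest valid grid cells, with linear temporal
interpolation between the bracketing layer dates (a same-date layer is
used directly, and a point at a cell center takes that cell's value
exactly).  A resampling null model produces simulated foraging locations
whose colony-distance, bearing and timestamp marginals match the observed
foraging points while their joint structure is randomized.  Suitability
from the fitted prey model is projected onto all points and averaged
within trips, which is the response variable of the seasonal analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rasters import RasterStack
from .sdm import CVResult

log = logging.getLogger(__name__)

__all__ = [
    "idw_annotate",
    "sample_background",
    "simulate_null_points",
    "project_suitability",
    "trip_mean_quality",
]


def _spatial_idw(stack: RasterStack, key: int, x: np.ndarray, y: np.ndarray,
                 k: int | None, power: float) -> np.ndarray:
    """IDW of one layer at planar points; ``k=None`` uses every cell."""
    g = stack.grid
    layer = stack.layers[key]
    out = np.empty(len(x))
    if k is None:
        X, Y = np.meshgrid(g.xcenters, g.ycenters)
        cx, cy, cv = X.ravel(), Y.ravel(), layer.ravel()
        for i in range(len(x)):
            d = np.hypot(cx - x[i], cy - y[i])
            hit = d < 1e-9
            if hit.any():
                out[i] = cv[np.argmax(hit)]
            else:
                w = d ** (-power)
                out[i] = (w @ cv) / w.sum()
        return out
    row, col = g.cell_index(x, y)
    half = max(2, int(np.ceil(np.sqrt(k))))  # window comfortably holds k nearest
    for i in range(len(x)):
        r0, r1 = max(row[i] - half, 0), min(row[i] + half + 1, g.ny)
        c0, c1 = max(col[i] - half, 0), min(col[i] + half + 1, g.nx)
        cxs = g.xcenters[c0:c1]
        cys = g.ycenters[r0:r1]
        vals = layer[r0:r1, c0:c1]
        ok = np.isfinite(vals)
        d = np.hypot(cxs[None, :] - x[i], cys[:, None] - y[i])
        d, vals = d[ok], vals[ok]
        if d.size == 0:
            out[i] = np.nan
            continue
        order = np.argsort(d)[:k]
        d, vals = d[order], vals[order]
        if d[0] < 1e-9:
            out[i] = vals[0]
        else:
            w = d ** (-power)
            out[i] = (w @ vals) / w.sum()
    return out


def idw_annotate(points: pd.DataFrame, stacks: dict[str, RasterStack],
                 k: int | None = 4, power: float = 2.0) -> pd.DataFrame:
    """Annotate points (x, y, year, day) with every stack's variable.

    Spatial interpolation is IDW over the k nearest valid cells; temporal
    interpolation is linear between the bracketing layer dates within the
    point's year.  Points whose neighbours are all missing are dropped
    with a log entry.
    """
    out = points.copy()
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    keyv = (points["year"].to_numpy(int) * 1000 + points["day"].to_numpy(int))
    for name, stack in stacks.items():
        vals = np.empty(len(points))
        for key in np.unique(keyv):
            sel = keyv == key
            lo, hi = stack.bracketing_days(int(key))
            vlo = _spatial_idw(stack, lo, x[sel], y[sel], k, power)
            if hi == lo:
                vals[sel] = vlo
            else:
                vhi = _spatial_idw(stack, hi, x[sel], y[sel], k, power)
                w = (key - lo) / (hi - lo)
                vals[sel] = (1 - w) * vlo + w * vhi
        out[name] = vals
    bad = out[list(stacks)].isna().any(axis=1)
    if bad.any():
        log.info("dropping %d points with no valid neighbours", int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    return out


def sample_background(stacks: dict[str, RasterStack], n: int, seed: int,
                      water_only: bool = True) -> pd.DataFrame:
    """Uniform background points over (water) cells and layer dates, annotated."""
    rng = np.random.default_rng(seed)
    bathy = stacks["bathy"]
    g = bathy.grid
    keys = np.array(stacks["sst"].days)
    b0 = bathy.layers[bathy.days[0]]
    mask = (b0 < 0) if water_only else np.isfinite(b0)
    ridx, cidx = np.nonzero(mask)
    if len(ridx) == 0:
        raise RuntimeError("no cells available for background sampling")
    pick = rng.integers(0, len(ridx), n)
    x = g.xcenters[cidx[pick]] + rng.uniform(-0.5, 0.5, n) * g.cell_size
    y = g.ycenters[ridx[pick]] + rng.uniform(-0.5, 0.5, n) * g.cell_size
    kp = keys[rng.integers(0, len(keys), n)]
    pts = pd.DataFrame({"year": kp // 1000, "day": kp % 1000, "x": x, "y": y})
    return idw_annotate(pts, stacks)


def simulate_null_points(foraging: pd.DataFrame, colony_xy: tuple[float, float],
                         n: int = 10_000, seed: int = 0,
                         bathy: RasterStack | None = None,
                         max_retries: int = 100,
                         joint: bool = False) -> pd.DataFrame:
    """Resampling null model of foraging locations.

    Each simulated point combines an independently resampled (with
    replacement) timestamp, colony bearing, and colony distance from the
    observed foraging-point marginals; its position is
    ``colony + distance * (cos a, sin a)``.  With ``joint=True`` whole
    observed rows are resampled instead.  When a bathymetry stack is
    given, points falling on land are redrawn up to ``max_retries`` times.
    Points are grouped into pseudo-trips by simulated date.
    """
    if len(foraging) == 0:
        raise ValueError("no observed foraging points to resample from")
    rng = np.random.default_rng(seed)
    cx, cy = colony_xy
    ang = np.arctan2(foraging["y"].to_numpy(float) - cy,
                     foraging["x"].to_numpy(float) - cx)
    dist = np.hypot(foraging["x"].to_numpy(float) - cx,
                    foraging["y"].to_numpy(float) - cy)
    years = foraging["year"].to_numpy(int)
    days = foraging["day"].to_numpy(int)
    tsec = foraging["t"].to_numpy(float) if "t" in foraging else np.zeros(len(foraging))
    m = len(foraging)

    it = rng.integers(0, m, n)
    if joint:
        ia = ib = it
    else:
        ia = rng.integers(0, m, n)
        ib = rng.integers(0, m, n)
    a, d = ang[ia], dist[ib]
    x = cx + d * np.cos(a)
    y = cy + d * np.sin(a)

    if bathy is not None:
        b0 = bathy.layers[bathy.days[0]]
        g = bathy.grid

        def on_land(xv, yv):
            inside = g.contains(xv, yv)
            row, col = g.cell_index(xv, yv)
            return ~inside | (b0[row, col] >= 0)

        bad = on_land(x, y)
        tries = 0
        while bad.any() and tries < max_retries:
            nb = int(bad.sum())
            ia2 = rng.integers(0, m, nb)
            ib2 = ia2 if joint else rng.integers(0, m, nb)
            a[bad], d[bad] = ang[ia2], dist[ib2]
            x[bad] = cx + d[bad] * np.cos(a[bad])
            y[bad] = cy + d[bad] * np.sin(a[bad])
            bad = on_land(x, y)
            tries += 1
        if bad.any():
            log.info("%d null points remain on land after %d retries",
                     int(bad.sum()), max_retries)

    out = pd.DataFrame({
        "bird_id": "sim",
        "year": years[it], "day": days[it], "t": tsec[it],
        "x": x, "y": y, "angle": a, "dist": d,
    })
    out["trip_id"] = ("sim_" + out["year"].astype(str) + "_"
                      + out["day"].astype(str).str.zfill(3))
    return out


def project_suitability(points: pd.DataFrame, cv: CVResult) -> pd.DataFrame:
    """Attach averaged cloglog suitability to annotated points."""
    missing = [v for v in cv.folds[0].model.variables if v not in points.columns]
    if missing:
        raise ValueError(f"points lack annotated variables: {missing}")
    out = points.copy()
    out["suitability"] = cv.predict(points)
    return out


def trip_mean_quality(points: pd.DataFrame, group: str) -> pd.DataFrame:
    """Mean suitability per trip: the trip-level habitat-quality response.

    Exact 0/1 means (impossible from cloglog but possible for externally
    supplied scores) are compressed into the open interval with the
    standard (S(n-1) + 0.5)/n shrinkage, n the number of trips.
    """
    if "suitability" not in points.columns:
        raise ValueError("points must carry a suitability column")
    gb = points.groupby(["trip_id"], sort=True)
    agg = gb.agg(bird_id=("bird_id", "first"), year=("year", "first"),
                 julian_day=("day", "first"), S=("suitability", "mean"))
    agg = agg.dropna(subset=["S"]).reset_index()
    n = len(agg)
    boundary = (agg["S"] <= 0) | (agg["S"] >= 1)
    if boundary.any() and n > 1:
        log.info("compressing %d boundary trip means", int(boundary.sum()))
        agg.loc[boundary, "S"] = (agg.loc[boundary, "S"] * (n - 1) + 0.5) / n
    agg["group"] = group
    return agg[["group", "year", "julian_day", "bird_id", "trip_id", "S"]]
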