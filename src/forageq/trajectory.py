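"""Raw GPS fixes → complete, colony-filtered, constant-step foraging trips.

Fixes are tidy tables (bird_id, timestamp, x, y) in planar projected
meters.  A *complete* foraging trip is a maximal run of consecutive fixes
outside the colony buffer, bracketed by colony fixes on the same calendar
day; colony/beach locations are removed from the path.  Trips are then
rediscretized to a constant step length (default 200 m) by linear
interpolation along the piecewise-linear path, which is the geometry the
first-passage-time stage assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Trip",
    "project_lonlat",
    "read_fixes",
    "dedupe_fixes",
    "segment_trips",
    "rediscretize",
    "rediscretize_all",
    "trips_to_frame",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class Trip:
    """One colony-to-colony excursion of a single bird.

    ``x, y`` are meters, ``t`` seconds since the epoch.  ``step_length``
    is None before rediscretization.
    """

    bird_id: str
    trip_id: str
    year: int
    day: int  # Julian day of year
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    step_length: float | None = None

    def __len__(self) -> int:
        return len(self.x)

    @property
    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


def project_lonlat(lon, lat, origin: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection to planar meters around ``origin``.

    Adequate at study-area scale (tens of km); distortion is second order
    in angular distance from the origin.
    """
    lon0, lat0 = origin
    lon = np.radians(np.asarray(lon, float) - lon0)
    lat = np.radians(np.asarray(lat, float))
    x = EARTH_RADIUS_M * np.cos(np.radians(lat0)) * lon
    y = EARTH_RADIUS_M * (lat - np.radians(lat0))
    return x, y


def read_fixes(path: str | Path, lonlat_origin: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read a Movebank-like fix CSV into the canonical fix table.

    Accepts either ``x``/``y`` (projected meters) or
    ``location-long``/``location-lat`` columns; the latter require
    ``lonlat_origin`` for projection.  Bird identity may be given as
    ``bird_id`` or ``individual-local-identifier``.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    bird = cols.get("bird_id") or cols.get("individual-local-identifier")
    if bird is None:
        raise ValueError("no bird identity column found")
    out = pd.DataFrame({
        "bird_id": df[bird].astype(str),
        "timestamp": pd.to_datetime(df[cols["timestamp"]]),
    })
    if "x" in cols and "y" in cols:
        out["x"] = df[cols["x"]].astype(float)
        out["y"] = df[cols["y"]].astype(float)
    elif "location-long" in cols and "location-lat" in cols:
        if lonlat_origin is None:
            raise ValueError("lon/lat input requires lonlat_origin")
        out["x"], out["y"] = project_lonlat(df[cols["location-long"]],
                                            df[cols["location-lat"]], lonlat_origin)
    else:
        raise ValueError("no coordinate columns found")
    return out


def dedupe_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Drop exact (bird, timestamp) duplicates, keeping the first; order kept."""
    return fixes.drop_duplicates(subset=["bird_id", "timestamp"], keep="first").reset_index(drop=True)


def segment_trips(fixes: pd.DataFrame, colony_xy: tuple[float, float],
                  colony_radius: float = 500.0) -> list[Trip]:
    """Isolate complete same-day foraging trips.

    A run of consecutive away-from-colony fixes becomes a trip when the
    fixes immediately before and after the run are colony fixes on the
    same calendar date as the whole run.  Runs that cross midnight or
    lack a bracketing colony fix (tag switched on away from the colony,
    or no same-day return) are discarded.  Colony fixes themselves are
    excluded from trip paths.
    """
    if len(fixes) == 0:
        return []
    cx, cy = colony_xy
    trips: list[Trip] = []
    for bird, sub in fixes.groupby("bird_id", sort=True):
        sub = sub.sort_values("timestamp")
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        ts = sub["timestamp"]
        at_colony = np.hypot(x - cx, y - cy) <= colony_radius
        dates = ts.dt.date.to_numpy()
        n = len(sub)
        i = 0
        k = 0
        while i < n:
            if at_colony[i]:
                i += 1
                continue
            j = i
            while j < n and not at_colony[j]:
                j += 1
            # run [i, j) away from colony
            same_day = len(set(dates[i:j])) == 1
            bracketed = (i > 0 and j < n
                         and dates[i - 1] == dates[i] and dates[j] == dates[j - 1])
            if same_day and bracketed:
                tsec = ts.iloc[i:j].astype("int64").to_numpy() / 1e9
                d = ts.iloc[i].dayofyear
                trips.append(Trip(
                    bird_id=str(bird), trip_id=f"{bird}_{k:03d}",
                    year=int(ts.iloc[i].year), day=int(d),
                    x=x[i:j].copy(), y=y[i:j].copy(), t=tsec))
                k += 1
            i = j
    return trips


def rediscretize(trip: Trip, step_length: float = 200.0) -> Trip:
    """Resample a trip to constant-step points along its path.

    Points are placed at arc-length positions 0, s, 2s, … with position
    and time linearly interpolated within the original segments, so the
    along-path spacing is exactly ``s`` (straight-line spacing between
    consecutive points is shorter where the path turns between samples).
    The original final endpoint is appended so the path ends at the
    colony approach; the final step may be shorter than ``s``.
    """
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    seg = np.hypot(np.diff(trip.x), np.diff(trip.y))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < step_length:
        raise ValueError(
            f"trip {trip.trip_id} path length {total:.1f} m < one step; degenerate")
    targets = np.arange(0.0, total, step_length)
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)
    x = np.interp(targets, arc, trip.x)
    y = np.interp(targets, arc, trip.y)
    t = np.interp(targets, arc, trip.t)
    return replace(trip, x=x, y=y, t=t, step_length=step_length)


def rediscretize_all(trips: list[Trip], step_length: float = 200.0) -> list[Trip]:
    """Rediscretize every trip, dropping (and logging) degenerate ones."""
    out = []
    for tr in trips:
        try:
            out.append(rediscretize(tr, step_length))
        except ValueError as e:
            log.info("excluding degenerate trip: %s", e)
    return out


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """Flatten trips to a tidy table (trip_id, seq, x, y, time)."""
    frames = []
    for tr in trips:
        frames.append(pd.DataFrame({
            "bird_id": tr.bird_id, "trip_id": tr.trip_id,
            "year": tr.year, "day": tr.day,
            "seq": np.arange(len(tr)), "x": tr.x, "y": tr.y, "t": tr.t,
        }))
    if not frames:
        return pd.DataFrame(columns=["bird_id", "trip_id", "year", "day", "seq", "x", "y", "t"])
    return pd.concat(frames, ignore_index=True)
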