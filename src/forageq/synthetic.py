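"""Seeded synthetic environments, prey presences, and forager tracks.

This module emulates the data-collection side of a colonial seabird
tracking study on a dynamic coastal prey landscape: gridded environmental
surfaces (sea surface temperature, chlorophyll-a, salinity, bathymetry),
presence records of prey schools, central-place forager GPS tracks with
two-mode (transit / area-restricted search) movement, and bird morphometry.
Every generator is a pure function of its configuration and a seed, and
ground truth (true suitability, behavioural mode of every fix) is exposed
so downstream detection and inference stages can be validated exactly.

The landscape follows known habitat associations of near-shore clupeid
prey: a sharp thermal rise in suitability between 30 and 32 °C, a
saturating chlorophyll-a response that plateaus at 10 mg/m³, and weak
unimodal responses to salinity and depth.  Seasonal warming plus a drift
in chlorophyll patches make overall habitat quality improve through the
season; a time-varying preference exponent lets simulated birds target
good habitat increasingly strongly, producing a differential improvement
of occupied patches over background — the signal the inference stage is
built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .rasters import GridSpec, RasterStack

__all__ = [
    "EnvScenario",
    "TruthParams",
    "generate_env",
    "true_suitability",
    "sample_prey_presences",
    "simulate_tracks",
    "generate_bird_metadata",
    "demo_scenario",
]

VARIABLES = ("sst", "chla", "sal", "bathy")


@dataclass(frozen=True)
class EnvScenario:
    """Spatial domain, dates and colony placement of a synthetic study.

    Coordinates are planar projected meters.  ``days`` are Julian days of
    year, shared by every year in ``years``.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(0.0, 0.0, 1000.0, 60, 60))
    years: tuple[int, ...] = (2015, 2016)
    days: tuple[int, ...] = tuple(range(120, 181, 2))
    colony_xy: tuple[float, float] = (30_000.0, 49_000.0)
    #: fraction of the domain height occupied by sea (southern part)
    coast_frac: float = 0.80

    def __post_init__(self) -> None:
        cx, cy = self.colony_xy
        if not self.grid.contains(cx, cy):
            raise ValueError("colony_xy outside extent")
        if len(self.days) < 2:
            raise ValueError("need at least two dates")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generating parameters for environment and behaviour."""

    # suitability response shapes
    sst_rise_range: tuple[float, float] = (30.0, 32.0)  # °C
    chla_plateau: float = 10.0  # mg/m³
    sal_opt: float = 30.0  # PSU
    sal_scale: float = 8.0
    bathy_opt: float = -12.0  # m, negative = below sea level
    bathy_scale: float = 18.0
    # environment dynamics
    sst_start: float = 30.2  # °C at first day of season (offshore edge)
    sst_end: float = 33.8  # °C at last day
    patch_count: int = 6
    patch_scale: float = 6000.0  # m, chlorophyll patch e-folding radius
    chla_log_mean: float = 1.3  # log mg/m³ baseline
    chla_log_sd: float = 1.1
    improvement_rate: float = 0.012  # per-day drift of log-chlorophyll level
    patch_drift: float = 250.0  # m/day centroid drift
    # behaviour
    transit_speed: float = 10.0  # m/s
    ars_speed: float = 0.9  # m/s
    ars_turn_sd: float = 1.6  # rad, step-to-step heading change in ARS
    transit_turn_sd: float = 0.08
    ars_patch_radius: float = 1500.0  # m
    fix_interval: float = 900.0  # s
    daylight: tuple[str, str] = ("06:00", "20:00")
    min_trip_dist: float = 4000.0  # m, nearest allowed destination
    ars_duration_range: tuple[float, float] = (7_200.0, 14_400.0)  # s
    # central-place range constraint: e-folding scale of the distance
    # taper on destination choice, relaxing from start to end of season
    # (tight nest attendance early, free-ranging late)
    range_scale_start: float = 5_000.0  # m
    range_scale_end: float = 60_000.0  # m
    #: chlorophyll patch centroids confined to this offshore fraction of
    #: the sea (prey schools concentrate off the coastal strip)
    patch_offshore_frac: float = 0.55

    def __post_init__(self) -> None:
        for name in ("chla_plateau", "patch_scale", "transit_speed", "ars_speed",
                     "ars_patch_radius", "fix_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# --------------------------------------------------------------------------
# environment


def _season_frac(days: Sequence[int]) -> Callable[[int], float]:
    d0, d1 = min(days), max(days)
    span = max(d1 - d0, 1)
    return lambda d: (d - d0) / span


def _coast_y(scenario: EnvScenario, x: np.ndarray) -> np.ndarray:
    """Coastline y-position: gently sinuous, land to the north."""
    g = scenario.grid
    base = g.y0 + scenario.coast_frac * (g.y1 - g.y0)
    return base + 0.03 * (g.y1 - g.y0) * np.sin(2 * np.pi * (x - g.x0) / (g.x1 - g.x0))


def bathymetry_field(scenario: EnvScenario) -> np.ndarray:
    """Static depth surface: negative at sea, deepening offshore."""
    g = scenario.grid
    X, Y = np.meshgrid(g.xcenters, g.ycenters)
    coast = _coast_y(scenario, X)
    # 1 m of depth per ~1.2 km offshore; positive (land) north of the coast
    return (Y - coast) / 1200.0 * 30.0 / ((g.y1 - g.y0) / 1200.0 / 1.6)


def generate_env(scenario: EnvScenario, truth: TruthParams, seed: int) -> dict[str, RasterStack]:
    """Generate the four-variable raster stack set for every (year, day).

    Layers are keyed by ``year * 1000 + julian_day`` so multiple seasons
    coexist in one stack.  Bathymetry is constant over time; sea surface
    temperature warms linearly through each season; chlorophyll-a is a
    log-Gaussian patch field whose level rises at ``improvement_rate`` per
    day and whose patch centroids drift; salinity is a fixed coastal
    gradient.
    """
    g = scenario.grid
    rng = np.random.default_rng(seed)
    X, Y = np.meshgrid(g.xcenters, g.ycenters)
    frac = _season_frac(scenario.days)
    d0 = min(scenario.days)

    bathy = bathymetry_field(scenario)
    coast = _coast_y(scenario, X)
    # fresher near the coast, saltier offshore, mild alongshore structure
    sal = (truth.sal_opt + 4.0
           - 8.0 * np.clip((Y - coast) / (g.y1 - g.y0), -1, 0)
           - 3.0 * np.cos(2 * np.pi * (X - g.x0) / (g.x1 - g.x0)))

    # mild static spatial SST texture, regenerated per year
    stacks = {v: RasterStack(v, g, {}) for v in VARIABLES}
    cells = g.cell_size
    for year in scenario.years:
        sst_texture = gaussian_filter(rng.standard_normal((g.ny, g.nx)), 4.0) * 2.0
        # chlorophyll patch centroids (at sea) and a smoothed noise floor
        n_p = truth.patch_count
        px = rng.uniform(g.x0, g.x1, n_p)
        py = rng.uniform(g.y0, g.y0 + truth.patch_offshore_frac
                         * scenario.coast_frac * (g.y1 - g.y0), n_p)
        pdir = rng.uniform(0, 2 * np.pi, n_p)
        noise = gaussian_filter(rng.standard_normal((g.ny, g.nx)),
                                truth.patch_scale / cells)
        noise /= max(noise.std(), 1e-12)
        for day in scenario.days:
            t = frac(day)
            key = year * 1000 + day
            # offshore (south) warms first; the thermal front reaches the
            # coastal strip near the colony only late in the season
            sst = (truth.sst_start + (truth.sst_end - truth.sst_start) * t
                   - 1.5 * (Y - g.y0) / (g.y1 - g.y0) + sst_texture * 0.3)
            # drifting patches
            dx = np.cos(pdir) * truth.patch_drift * (day - d0)
            dy = np.sin(pdir) * truth.patch_drift * (day - d0)
            bumps = np.zeros_like(X)
            for j in range(n_p):
                r2 = (X - (px[j] + dx[j])) ** 2 + (Y - (py[j] + dy[j])) ** 2
                bumps += np.exp(-r2 / (2 * truth.patch_scale ** 2))
            fld = bumps / max(bumps.std(), 1e-12) + 0.6 * noise
            fld /= max(fld.std(), 1e-12)
            chla = np.exp(truth.chla_log_mean
                          + truth.improvement_rate * (day - d0)
                          + truth.chla_log_sd * fld)
            stacks["sst"].layers[key] = sst
            stacks["chla"].layers[key] = chla
            stacks["sal"].layers[key] = np.broadcast_to(sal, sst.shape).copy()
            stacks["bathy"].layers[key] = bathy.copy()
    return stacks


def true_suitability(sst, chla, sal, bathy, truth: TruthParams) -> np.ndarray:
    """Closed-form generating suitability in [0, 1].

    The product of four per-variable responses: a logistic ramp in SST
    concentrated on ``sst_rise_range``; a smoothstep in chlorophyll-a that
    is exactly flat at and above ``chla_plateau``; weak unimodal Gaussian
    responses in salinity and depth; and a soft water gate that sends
    suitability to ~0 on land (bathymetry above sea level).
    """
    sst = np.asarray(sst, float)
    chla = np.asarray(chla, float)
    sal = np.asarray(sal, float)
    bathy = np.asarray(bathy, float)

    lo, hi = truth.sst_rise_range
    mid, width = 0.5 * (lo + hi), (hi - lo) / 8.0
    r_sst = 1.0 / (1.0 + np.exp(-(sst - mid) / width))

    u = np.clip(chla / truth.chla_plateau, 0.0, 1.0)
    r_chla = u * u * (3.0 - 2.0 * u)

    r_sal = 0.7 + 0.3 * np.exp(-(((sal - truth.sal_opt) / truth.sal_scale) ** 2))
    r_bathy = (0.7 + 0.3 * np.exp(-(((bathy - truth.bathy_opt) / truth.bathy_scale) ** 2)))
    water = 1.0 / (1.0 + np.exp(bathy / 1.5))  # ~1 at sea, ~0 on land
    return np.clip(r_sst * r_chla * r_sal * r_bathy * water, 0.0, 1.0)


def suitability_field(stacks: dict[str, RasterStack], key: int, truth: TruthParams) -> np.ndarray:
    """True suitability evaluated on the full grid for one (year, day) key."""
    return true_suitability(stacks["sst"].layers[key], stacks["chla"].layers[key],
                            stacks["sal"].layers[key], stacks["bathy"].layers[key], truth)


# --------------------------------------------------------------------------
# prey presences


def sample_prey_presences(stacks: dict[str, RasterStack], truth: TruthParams,
                          n: int, seed: int, max_batches: int = 2000) -> pd.DataFrame:
    """Thinned sampling of prey presence points.

    Candidate points are uniform over the extent and over layer dates;
    each is accepted with probability equal to the true suitability at
    its position and date, so presence density is proportional to
    suitability.  Returns columns year, day, x, y.
    """
    if n == 0:
        return pd.DataFrame(columns=["year", "day", "x", "y"])
    if n < 0:
        raise ValueError("n must be >= 0")
    grid = stacks["sst"].grid
    keys = stacks["sst"].days
    smax = max(float(suitability_field(stacks, k, truth).max()) for k in keys)
    if smax <= 0:
        raise RuntimeError("true suitability is identically zero; cannot sample presences")
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_batches):
        m = max(256, int(1.5 * (n - got) / max(smax / 4, 1e-3)))
        m = min(m, 200_000)
        ki = rng.integers(0, len(keys), m)
        x = rng.uniform(grid.x0, grid.x1, m)
        y = rng.uniform(grid.y0, grid.y1, m)
        row, col = grid.cell_index(x, y)
        s = np.empty(m)
        for j, k in enumerate(keys):
            sel = ki == j
            if sel.any():
                fld = suitability_field(stacks, k, truth)
                s[sel] = fld[row[sel], col[sel]]
        keep = rng.uniform(size=m) < s
        kk = np.array(keys)[ki[keep]]
        out.append(np.column_stack([kk // 1000, kk % 1000, x[keep], y[keep]]))
        got += int(keep.sum())
        if got >= n:
            break
    else:
        raise RuntimeError("presence sampling did not reach n within batch cap")
    arr = np.concatenate(out)[:n]
    return pd.DataFrame(arr, columns=["year", "day", "x", "y"]).astype(
        {"year": int, "day": int})


# --------------------------------------------------------------------------
# tracks


def _clock_seconds(hhmm: str) -> float:
    h, m = hhmm.split(":")
    return 3600.0 * int(h) + 60.0 * int(m)


def simulate_tracks(scenario: EnvScenario, truth: TruthParams,
                    stacks: dict[str, RasterStack], n_birds: int,
                    preference: Callable[[float], float], seed: int,
                    trip_prob: float = 0.9) -> pd.DataFrame:
    """Simulate central-place forager GPS fixes with known behavioural mode.

    Each bird makes at most one round trip per layer date: outbound
    transit (fast, nearly straight) to a destination cell, an
    area-restricted search bout (slow, tortuous, confined within
    ``ars_patch_radius`` of the destination), and a straight return to
    the colony.  The destination is drawn over reachable water with
    weight ``suitability ** preference(t) * exp(-distance / L(t))``,
    where ``t`` is the 0-1 season fraction and the range scale L(t)
    relaxes from ``range_scale_start`` to ``range_scale_end`` — tight
    nest attendance early in the season, free-ranging and increasingly
    quality-directed choice late.  Fixes are emitted every
    ``fix_interval`` seconds inside the daylight window, starting and
    ending at the colony on the same day.

    Returns a tidy fix table: bird_id, timestamp, x, y, year, day, mode
    (colony | transit | ars), with mode the ground-truth label.
    """
    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    g = scenario.grid
    cx, cy = scenario.colony_xy
    if not g.contains(cx, cy):
        raise ValueError("colony outside extent")
    rng = np.random.default_rng(seed)
    frac = _season_frac(scenario.days)
    day_start = _clock_seconds(truth.daylight[0])
    day_end = _clock_seconds(truth.daylight[1])
    dt = truth.fix_interval

    bathy = stacks["bathy"].layers[stacks["bathy"].days[0]]
    X, Y = np.meshgrid(g.xcenters, g.ycenters)
    dist_colony = np.hypot(X - cx, Y - cy)
    # reachable water: at sea, far enough to be a real trip, near enough
    # that out + ARS + back fits in daylight
    budget = day_end - day_start - truth.ars_duration_range[1] - 2 * dt
    max_range = 0.45 * budget * truth.transit_speed
    reachable = (bathy < 0) & (dist_colony > truth.min_trip_dist) & (dist_colony < max_range)
    if not reachable.any():
        raise RuntimeError("no reachable water cells from the colony")

    rows = []
    for b in range(n_birds):
        bird = f"bird{b:02d}"
        for year in scenario.years:
            for day in scenario.days:
                if rng.uniform() > trip_prob:
                    continue
                key = year * 1000 + day
                t = frac(day)
                s = suitability_field(stacks, key, truth)
                L = (truth.range_scale_start
                     + (truth.range_scale_end - truth.range_scale_start) * t)
                w = np.where(reachable,
                             np.power(np.maximum(s, 1e-12), preference(t))
                             * np.exp(-dist_colony / L), 0.0)
                tot = w.sum()
                if tot <= 0:
                    continue
                idx = rng.choice(w.size, p=(w / tot).ravel())
                ry, rx = np.unravel_index(idx, w.shape)
                dest = (X[ry, rx] + rng.uniform(-0.5, 0.5) * g.cell_size,
                        Y[ry, rx] + rng.uniform(-0.5, 0.5) * g.cell_size)
                ars_dur = rng.uniform(*truth.ars_duration_range)
                t0 = day_start + rng.uniform(0, 2) * 3600.0
                fixes = _one_trip(rng, truth, (cx, cy), dest, ars_dur)
                for i, (px, py, mode) in enumerate(fixes):
                    ts = t0 + i * dt
                    if ts > day_end:
                        break
                    rows.append((bird, year, day, ts, px, py, mode))

    df = pd.DataFrame(rows, columns=["bird_id", "year", "day", "t", "x", "y", "mode"])
    base = pd.to_datetime(df["year"].astype(str), format="%Y")
    df["timestamp"] = (base + pd.to_timedelta(df["day"] - 1, unit="D")
                       + pd.to_timedelta(df["t"], unit="s"))
    return df.drop(columns="t")[["bird_id", "timestamp", "x", "y", "year", "day", "mode"]]


def _one_trip(rng, truth: TruthParams, colony, dest, ars_duration):
    """Fix-interval-resolution positions for one round trip."""
    dt = truth.fix_interval
    cx, cy = colony
    dxm, dym = dest
    out = [(cx, cy, "colony")]
    # outbound transit: straight with small heading noise
    x, y = cx, cy
    heading = np.arctan2(dym - y, dxm - x)
    while np.hypot(dxm - x, dym - y) > truth.transit_speed * dt:
        heading = np.arctan2(dym - y, dxm - x) + rng.normal(0, truth.transit_turn_sd)
        x += truth.transit_speed * dt * np.cos(heading)
        y += truth.transit_speed * dt * np.sin(heading)
        out.append((x, y, "transit"))
    x, y = dxm, dym
    out.append((x, y, "ars"))
    # ARS: slow correlated walk confined to the patch
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(int(ars_duration // dt)):
        heading += rng.normal(0, truth.ars_turn_sd)
        nx = x + truth.ars_speed * dt * np.cos(heading)
        ny = y + truth.ars_speed * dt * np.sin(heading)
        if np.hypot(nx - dxm, ny - dym) > truth.ars_patch_radius:
            heading = np.arctan2(dym - y, dxm - x) + rng.normal(0, 0.5)
            nx = x + truth.ars_speed * dt * np.cos(heading)
            ny = y + truth.ars_speed * dt * np.sin(heading)
        x, y = nx, ny
        out.append((x, y, "ars"))
    # return transit straight to the colony
    while np.hypot(cx - x, cy - y) > truth.transit_speed * dt:
        heading = np.arctan2(cy - y, cx - x)
        x += truth.transit_speed * dt * np.cos(heading)
        y += truth.transit_speed * dt * np.sin(heading)
        out.append((x, y, "transit"))
    out.append((cx, cy, "colony"))
    return out


# --------------------------------------------------------------------------
# bird metadata


def generate_bird_metadata(n_birds: int, seed: int,
                           mass_range: tuple[float, float] = (2600.0, 4330.0),
                           noise_sd: float = 0.04) -> pd.DataFrame:
    """Bird id, sex, body mass (g) and tarsus length (mm).

    Tarsus is lognormal around a sex-specific mean; mass follows a cubic
    allometry on tarsus with lognormal noise, clipped into ``mass_range``.
    With ``noise_sd=0`` mass is exactly proportional to tarsus cubed (a
    degenerate control for condition-index code paths).
    """
    if n_birds <= 0:
        raise ValueError("n_birds must be positive")
    rng = np.random.default_rng(seed)
    sex = np.where(rng.uniform(size=n_birds) < 0.5, "F", "M")
    tarsus_mu = np.where(sex == "F", 92.0, 100.0)
    tarsus = tarsus_mu * np.exp(rng.normal(0, 0.03, n_birds))
    mid = 0.5 * (mass_range[0] + mass_range[1])
    mass = mid * (tarsus / tarsus_mu) ** 3 * np.exp(rng.normal(0, noise_sd, n_birds))
    mass = np.clip(mass, *mass_range)
    return pd.DataFrame({
        "bird_id": [f"bird{i:02d}" for i in range(n_birds)],
        "sex": sex,
        "mass_g": mass,
        "tarsus_mm": tarsus,
    })


# --------------------------------------------------------------------------
# packaged demo scenario


def demo_scenario() -> tuple[EnvScenario, TruthParams]:
    """The packaged small demo: 60×60 km domain at 1 km cells, two seasons."""
    return EnvScenario(), TruthParams()


def demo_preference(t: float) -> float:
    """Season-increasing habitat preference exponent for the demo birds.

    Near-random patch choice early in the season (exponent ~0), strongly
    quality-directed late (exponent ~6).  Together with the relaxing
    central-place range constraint this makes occupied-patch quality start
    below the landscape null (birds confined to the cool coastal strip)
    and outpace it late in the season.
    """
    return 6.0 * t ** 2
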