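"""Gridded environmental surfaces indexed by date.

A :class:`RasterStack` holds one environmental variable (e.g. sea surface
temperature) on a fixed planar grid, with one layer per date.  Coordinates
are projected meters; the grid is cell-center registered.  Layers are
written to disk as single-band TIFF files (one per date, date in the
filename) with a JSON sidecar carrying the georeferencing, so a stack
round-trips without any GIS dependency.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["GridSpec", "RasterStack"]


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a planar grid.

    Parameters
    ----------
    x0, y0 : float
        Lower-left corner of the extent, in projected meters.
    cell_size : float
        Square cell edge, meters.
    nx, ny : int
        Number of columns / rows.
    """

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nx <= 1 or self.ny <= 1:
            raise ValueError(
                f"degenerate extent: need >1 cell per axis, got {self.nx}x{self.ny}"
            )

    @property
    def x1(self) -> float:
        return self.x0 + self.nx * self.cell_size

    @property
    def y1(self) -> float:
        return self.y0 + self.ny * self.cell_size

    @property
    def xcenters(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def ycenters(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def cell_index(self, x, y):
        """Row/column of the cell containing (x, y); clipped to the grid."""
        col = np.clip(((np.asarray(x, float) - self.x0) // self.cell_size).astype(int), 0, self.nx - 1)
        row = np.clip(((np.asarray(y, float) - self.y0) // self.cell_size).astype(int), 0, self.ny - 1)
        return row, col


@dataclass
class RasterStack:
    """Per-date layers of one environmental variable on a common grid.

    ``layers`` maps integer Julian day -> (ny, nx) float array, rows running
    south-to-north (row 0 at y0).
    """

    name: str
    grid: GridSpec
    layers: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for day, arr in self.layers.items():
            if arr.shape != (self.grid.ny, self.grid.nx):
                raise ValueError(f"layer {day} shape {arr.shape} != grid {(self.grid.ny, self.grid.nx)}")

    @property
    def days(self) -> list[int]:
        return sorted(self.layers)

    def layer(self, day: int) -> np.ndarray:
        return self.layers[day]

    def bracketing_days(self, day: int) -> tuple[int, int]:
        """Nearest layer dates on or around ``day`` (equal on exact hit)."""
        days = np.array(self.days)
        if day in self.layers:
            return day, day
        lo = days[days < day]
        hi = days[days > day]
        if lo.size == 0 and hi.size == 0:
            raise KeyError(f"stack '{self.name}' has no layers")
        if lo.size == 0:
            return int(hi[0]), int(hi[0])
        if hi.size == 0:
            return int(lo[-1]), int(lo[-1])
        return int(lo[-1]), int(hi[0])

    # ---- disk round trip -------------------------------------------------
    def write(self, directory: str | Path) -> None:
        """Write one single-band TIFF per date plus a JSON grid sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "name": self.name,
            "x0": self.grid.x0,
            "y0": self.grid.y0,
            "cell_size": self.grid.cell_size,
            "nx": self.grid.nx,
            "ny": self.grid.ny,
        }
        (directory / f"{self.name}.grid.json").write_text(json.dumps(meta, indent=1))
        for day in self.days:
            tifffile.imwrite(
                directory / f"{self.name}_day{day:03d}.tif",
                self.layers[day].astype(np.float32),
            )

    @classmethod
    def read(cls, directory: str | Path, name: str) -> "RasterStack":
        directory = Path(directory)
        meta = json.loads((directory / f"{name}.grid.json").read_text())
        grid = GridSpec(meta["x0"], meta["y0"], meta["cell_size"], meta["nx"], meta["ny"])
        layers = {}
        pat = re.compile(rf"{re.escape(name)}_day(\d+)\.tif$")
        for p in sorted(directory.glob(f"{name}_day*.tif")):
            m = pat.search(p.name)
            if m:
                layers[int(m.group(1))] = np.asarray(tifffile.imread(p), dtype=float)
        return cls(name=name, grid=grid, layers=layers)
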