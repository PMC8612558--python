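"""Lightweight georeferenced raster container and TIFF I/O.

Rasters are written as plain (uncompressed or deflate) TIFFs with an ESRI
world file (``.tfw``) and a one-line ``.prj`` sidecar holding the project
CRS identifier, so every georeferencing component stays in text form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .crs import CEA, Affine
from .errors import ParameterError


@dataclass
class Raster:
    """A single-band raster: 2-D array + affine transform + CRS id."""

    grid: np.ndarray
    transform: Affine
    crs: str = CEA

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ParameterError("raster grid must be 2-D")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def pixel_width(self) -> float:
        return abs(self.transform.a)

    @property
    def pixel_height(self) -> float:
        return abs(self.transform.e)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in squared CRS units."""
        return self.pixel_width * self.pixel_height

    def aligned_with(self, other: "Raster") -> bool:
        return (self.shape == other.shape and self.crs == other.crs
                and self.transform == other.transform)

    def centers(self):
        """(x, y) arrays of all pixel centres, each of raster shape."""
        rows, cols = np.mgrid[0:self.shape[0], 0:self.shape[1]]
        return self.transform.xy(rows, cols)

    def rowcol_at(self, x, y):
        """Integer (row, col) of the cell *containing* each point.

        Points outside the grid get row/col = -1.
        """
        row_f, col_f = self.transform.rowcol(x, y)
        row = np.floor(row_f).astype(int)
        col = np.floor(col_f).astype(int)
        bad = (row < 0) | (row >= self.shape[0]) | (col < 0) | (col >= self.shape[1])
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def sample(self, x, y, fill=np.nan):
        """Value of the containing cell at each point (no interpolation).

        This is the 1 km-cell point extraction used for annotating presence
        records with elevation and tree cover; out-of-grid points get
        ``fill``.
        """
        row, col = self.rowcol_at(x, y)
        out = np.where(row >= 0,
                       self.grid[np.clip(row, 0, None), np.clip(col, 0, None)],
                       fill)
        return out

    def bounds(self):
        """(west, south, east, north) of the full grid extent."""
        nrow, ncol = self.shape
        x0, y0 = self.transform * (0, 0)
        x1, y1 = self.transform * (ncol, nrow)
        return (min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))


def write_raster(raster: Raster, path) -> Path:
    """Write TIFF + world file + .prj sidecar; returns the TIFF path."""
    path = Path(path)
    grid = raster.grid
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    tifffile.imwrite(path, grid)
    t = raster.transform
    # world file convention: line 5/6 hold the CENTER of the UL pixel
    cx, cy = t.xy(0, 0)
    world = "\n".join(f"{v:.10f}" for v in (t.a, t.d, t.b, t.e, float(cx), float(cy)))
    path.with_suffix(".tfw").write_text(world + "\n")
    path.with_suffix(".prj").write_text(raster.crs + "\n")
    return path


def read_raster(path) -> Raster:
    """Read a TIFF written by :func:`write_raster` (sidecars required)."""
    path = Path(path)
    grid = tifffile.imread(path)
    tfw = path.with_suffix(".tfw")
    if not tfw.exists():
        raise ParameterError(f"missing world file: {tfw}")
    a, d, b, e, cx, cy = (float(v) for v in tfw.read_text().split())
    transform = Affine(a, b, cx - a / 2 - b / 2, d, e, cy - d / 2 - e / 2)
    prj = path.with_suffix(".prj")
    crs = prj.read_text().strip() if prj.exists() else CEA
    if not crs:
        warnings.warn(f"empty .prj for {path}; assuming {CEA}")
        crs = CEA
    return Raster(grid=grid, transform=transform, crs=crs)
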