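"""Habitat refinement: elevational limits, tree-cover threshold, AOH raster.

The Area of Habitat (AOH) is the intersection, inside the alpha hull, of
the pixels whose elevation falls within the species' final elevational
limits and (for forest species) whose tree cover meets the estimated
threshold.

Elevational limits: the 1st and 99th percentiles of the elevations at the
presence points (trimming the extreme 1% guards against mislocated records
such as nearby peaks or settlements), enveloped with the documented Red
List elevations — the smaller value becomes the minimum and the larger the
maximum.

Tree-cover threshold: zero-cover presences are discarded (they typically
mark lodges or trailheads rather than the bird's location); the habitat
interval is the upper 75% of the remaining observed values, i.e. the
threshold is the 25th percentile of the nonzero covers.

All percentiles use the linear-interpolation convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage

from .crs import lonlat_to_cea, CEA, WGS84
from .errors import DegenerateInputError, ParameterError
from .ingest import PresenceSet, SpeciesMeta
from .raster import Raster


def annotate_presences(presences: PresenceSet, elevation: Raster,
                       cover: Raster) -> PresenceSet:
    """Fill each point's elevation/cover from its containing 1 km cell."""
    for p in presences.points:
        if elevation.crs == CEA:
            x, y = lonlat_to_cea(p.lon, p.lat)
        else:
            x, y = p.lon, p.lat
        p.elevation = float(elevation.sample(x, y))
        p.cover = float(cover.sample(x, y))
    return presences


@dataclass
class ElevationLimits:
    """Observed percentile limits enveloped with documented limits (m)."""

    observed_p01: float
    observed_p99: float
    documented_min: Optional[float]
    documented_max: Optional[float]
    final_min: float
    final_max: float


def elevation_limits(presences: PresenceSet,
                     meta: Optional[SpeciesMeta] = None) -> ElevationLimits:
    """Estimate the species' final elevational range.

    Uses the habitat subset of presences (on/after the date floor).  With
    no documented limits the final limits equal the observed percentiles;
    a documented limit on one side widens that side only (one-sided
    envelope).
    """
    elevs = np.array([p.elevation for p in presences.habitat_points()
                      if p.elevation is not None and np.isfinite(p.elevation)])
    if elevs.size == 0:
        raise DegenerateInputError("no annotated presences for elevation limits")
    p01, p99 = np.percentile(elevs, [1, 99])  # linear interpolation
    doc_min = meta.documented_elev_min if meta else None
    doc_max = meta.documented_elev_max if meta else None
    final_min = p01 if doc_min is None else min(p01, doc_min)
    final_max = p99 if doc_max is None else max(p99, doc_max)
    return ElevationLimits(observed_p01=float(p01), observed_p99=float(p99),
                           documented_min=doc_min, documented_max=doc_max,
                           final_min=float(final_min),
                           final_max=float(final_max))


@dataclass
class HabitatThreshold:
    """Minimum tree cover (percent) defining suitable forest habitat."""

    cover_min: float
    n_values_used: int
    zeros_excluded: int


def cover_threshold(presences: PresenceSet) -> HabitatThreshold:
    """Tree-cover threshold from the habitat subset of presences.

    Raises :class:`DegenerateInputError` when every cover value is zero;
    the caller then flags the species for elevation-only mapping.
    """
    covers = np.array([p.cover for p in presences.habitat_points()
                       if p.cover is not None and np.isfinite(p.cover)])
    if covers.size == 0:
        raise DegenerateInputError("no annotated presences for cover threshold")
    nonzero = covers[covers > 0]
    zeros = int(covers.size - nonzero.size)
    if nonzero.size == 0:
        raise DegenerateInputError(
            "all presence covers are zero; species needs elevation-only mode")
    cover_min = float(np.percentile(nonzero, 25))
    return HabitatThreshold(cover_min=cover_min,
                            n_values_used=int(nonzero.size),
                            zeros_excluded=zeros)


def resample_cover(fine: Raster, target: Raster) -> Raster:
    """Bilinearly resample a fine cover raster onto the target's 1 km grid.

    ``target`` supplies the output grid geometry only; its values are
    ignored.  Both rasters must share a CRS and overlap.
    """
    if fine.crs != target.crs:
        raise ParameterError("resample requires matching CRS "
                             f"({fine.crs!r} vs {target.crs!r})")
    fb, tb = fine.bounds(), target.bounds()
    if fb[2] <= tb[0] or tb[2] <= fb[0] or fb[3] <= tb[1] or tb[3] <= fb[1]:
        raise ParameterError("raster extents do not overlap")
    xc, yc = target.centers()
    row_f, col_f = fine.transform.rowcol(xc, yc)
    # map_coordinates indexes pixel centres at integers; rowcol() returns
    # fractional indices where the centre sits at +0.5
    coords = np.stack([row_f - 0.5, col_f - 0.5])
    out = ndimage.map_coordinates(fine.grid.astype(float), coords, order=1,
                                  mode="nearest")
    return Raster(grid=np.clip(out, 0.0, 100.0), transform=target.transform,
                  crs=target.crs)


@dataclass
class AOHMask:
    """Per-pixel Area-of-Habitat mask on the project grid.

    ``grid`` is boolean: True = AOH, False = outside.  ``mode`` records
    whether tree cover participated ('forest') or only elevation did
    ('elevation_only', used for open-habitat species).
    """

    grid: np.ndarray
    transform: "object"
    crs: str
    mode: str

    @property
    def shape(self):
        return self.grid.shape

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())

    def pixel_area_km2(self) -> float:
        t = self.transform
        return abs(t.a * t.e) / 1e6 if self.crs == CEA else float("nan")

    def area_km2(self) -> float:
        return self.n_pixels * self.pixel_area_km2()

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid.astype(np.uint8),
                      transform=self.transform, crs=self.crs)


def hull_pixel_mask(hull_geom_cea, grid: Raster) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside/on the hull."""
    if hull_geom_cea is None or hull_geom_cea.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    xc, yc = grid.centers()
    shapely.prepare(hull_geom_cea)
    return shapely.intersects_xy(hull_geom_cea, xc, yc)


def compute_aoh(hull_geom_cea, elevation: Raster, cover: Raster,
                limits: ElevationLimits,
                threshold: Optional[HabitatThreshold],
                mode: str = "forest") -> AOHMask:
    """Rasterize the Area of Habitat inside the hull.

    A pixel is AOH iff its centre lies in the hull, its elevation is within
    the final limits (inclusive), and — in forest mode — its cover meets
    the threshold.  An empty AOH is valid but triggers a warning.
    """
    if mode not in ("forest", "elevation_only"):
        raise ParameterError(f"unknown AOH mode '{mode}'")
    if not elevation.aligned_with(cover):
        raise ParameterError("elevation and cover rasters are not co-registered")
    inside = hull_pixel_mask(hull_geom_cea, elevation)
    ok_elev = ((elevation.grid >= limits.final_min)
               & (elevation.grid <= limits.final_max))
    mask = inside & ok_elev
    if mode == "forest":
        if threshold is None:
            raise ParameterError("forest mode requires a cover threshold")
        mask &= cover.grid >= threshold.cover_min
    if not mask.any():
        warnings.warn("Area of Habitat is empty for this species")
    return AOHMask(grid=mask, transform=elevation.transform,
                   crs=elevation.crs, mode=mode)
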