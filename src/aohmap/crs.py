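"""Coordinate handling for the pipeline.

All metric work (alpha values, nearest-neighbour distances, areas in km²)
happens in a world Lambert cylindrical equal-area projection on the authalic
sphere.  The projection is exactly area-preserving, so a 1000 m × 1000 m
pixel is exactly 1 km² at any latitude, which makes analytic area checks in
the tests exact.  Geographic coordinates are WGS84 longitude/latitude.

CRS identifiers used throughout: ``"wgs84"`` (degrees) and ``"cea"``
(metres, cylindrical equal-area, standard parallel 0°).
"""

from __future__ import annotations

import numpy as np
import shapely.ops

#: Authalic Earth radius in metres (sphere with the WGS84 ellipsoid's area).
EARTH_RADIUS_M = 6_371_007.1809

WGS84 = "wgs84"
CEA = "cea"


def lonlat_to_cea(lon, lat):
    """Project WGS84 degrees to cylindrical equal-area metres.

    ``x = R·λ``, ``y = R·sin(φ)``.  Accepts scalars or arrays.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_M * np.radians(lon)
    y = EARTH_RADIUS_M * np.sin(np.radians(lat))
    return x, y


def cea_to_lonlat(x, y):
    """Inverse of :func:`lonlat_to_cea`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / EARTH_RADIUS_M)
    lat = np.degrees(np.arcsin(np.clip(y / EARTH_RADIUS_M, -1.0, 1.0)))
    return lon, lat


def geom_to_cea(geom):
    """Reproject a shapely geometry from WGS84 to the equal-area CRS."""
    return shapely.ops.transform(lonlat_to_cea, geom)


def geom_to_wgs84(geom):
    """Reproject a shapely geometry from the equal-area CRS to WGS84."""
    return shapely.ops.transform(cea_to_lonlat, geom)


class Affine:
    """Minimal 2-D affine georeferencing transform.

    Maps (col, row) pixel indices to world coordinates of the pixel's
    *upper-left corner*: ``x = a·col + b·row + c``, ``y = d·col + e·row + f``.
    The common north-up raster has ``b = d = 0``, ``a > 0`` and ``e < 0``.
    """

    __slots__ = ("a", "b", "c", "d", "e", "f")

    def __init__(self, a, b, c, d, e, f):
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.d, self.e, self.f = float(d), float(e), float(f)

    @classmethod
    def from_origin(cls, west, north, xsize, ysize):
        """North-up transform with pixel size ``xsize`` × ``ysize`` (> 0)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def __mul__(self, colrow):
        col, row = colrow
        return (self.a * col + self.b * row + self.c,
                self.d * col + self.e * row + self.f)

    def xy(self, row, col, offset="center"):
        """World coordinates of a pixel; ``offset`` is 'center' or 'ul'."""
        shift = 0.5 if offset == "center" else 0.0
        return self * (np.asarray(col) + shift, np.asarray(row) + shift)

    def rowcol(self, x, y):
        """Fractional (row, col) of world coordinates (north-up only)."""
        if self.b or self.d:
            raise NotImplementedError("rotated transforms not supported")
        col = (np.asarray(x, dtype=float) - self.c) / self.a
        row = (np.asarray(y, dtype=float) - self.f) / self.e
        return row, col

    def to_tuple(self):
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    def __eq__(self, other):
        return isinstance(other, Affine) and self.to_tuple() == other.to_tuple()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Affine{self.to_tuple()}"
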