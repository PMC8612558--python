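"""Alpha-hull range envelopes.

The range envelope for a species is an alpha hull built over the union of
the published-range polygon vertices and the qualifying presence points.
The alpha hull generalizes the convex hull: the boundary "pinches in"
around the data, with infinite alpha recovering the minimum convex polygon
and very small alpha fragmenting the shape into per-cluster pieces.

The alpha value is chosen per species as the median of all pairwise
presence–presence distances ("median inter-presence distance"), computed on
the presence points only, in the project's equal-area projection.

Implementation: the hull is the union of Delaunay triangles whose
circumradius is at most alpha (the 2-D alpha complex).  Input points are
deduplicated and lexicographically sorted first, so the result is invariant
to input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .crs import geom_to_cea, geom_to_wgs84
from .errors import DegenerateInputError


@dataclass
class AlphaHull:
    """Alpha-hull envelope in the equal-area CRS (and WGS84 mirror)."""

    geometry: shapely.Geometry          # equal-area metres
    geometry_wgs84: shapely.Geometry
    alpha_km: float
    n_input_points: int
    fallback_used: bool = False


def _distinct(points: np.ndarray) -> np.ndarray:
    """Deduplicate and lexicographically sort an (n, 2) point array."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    return np.unique(points, axis=0)


def median_interpoint_distance(points_xy: np.ndarray) -> float:
    """Median over all pairwise distances, in km.

    ``points_xy`` is an (n, 2) array in equal-area metres.  Requires at
    least two distinct points; otherwise raises
    :class:`DegenerateInputError` (the caller falls back to a buffered
    range union).
    """
    pts = _distinct(points_xy)
    if len(pts) < 2:
        raise DegenerateInputError(
            "median inter-presence distance needs >= 2 distinct points")
    return float(np.median(pdist(pts))) / 1000.0


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[-1] <= tol * max(s[0], 1.0)


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle (inf for degenerate ones)."""
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
             - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def build_alpha_hull(points_xy: np.ndarray, alpha_km: float) -> AlphaHull:
    """Alpha hull of points (equal-area metres) with radius ``alpha_km``.

    Monotone in alpha (larger alpha never shrinks the hull); at very large
    alpha the result equals the convex hull.  Fewer than three non-collinear
    points raise :class:`DegenerateInputError` — callers should use
    :func:`species_hull`, which applies the buffered-range fallback.
    """
    if alpha_km <= 0:
        raise DegenerateInputError("alpha must be positive")
    pts = _distinct(points_xy)
    if len(pts) < 3 or _collinear(pts):
        raise DegenerateInputError(
            "alpha hull needs >= 3 non-collinear points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # near-degenerate input qhull refuses
        raise DegenerateInputError(str(exc)) from exc
    alpha_m = alpha_km * 1000.0
    # an alpha ball wider than the point set can never pinch the boundary:
    # the hull is exactly the minimum convex polygon (this also sidesteps
    # sliver triangles whose circumradius overflows any finite alpha)
    span = pts.max(axis=0) - pts.min(axis=0)
    if alpha_m >= float(np.hypot(*span)):
        geom = shapely.MultiPoint(pts).convex_hull
    else:
        radii = _circumradii(pts, tri.simplices)
        keep = tri.simplices[radii <= alpha_m]
        triangles = [Polygon(pts[s]) for s in keep]
        geom = unary_union(triangles) if triangles else MultiPolygon([])
    if not geom.is_valid:
        geom = geom.buffer(0)
    return AlphaHull(geometry=geom, geometry_wgs84=geom_to_wgs84(geom),
                     alpha_km=float(alpha_km), n_input_points=len(pts))


def range_vertices(range_geom_wgs84) -> np.ndarray:
    """All polygon vertices (rings and holes) projected to equal-area, (n,2)."""
    if range_geom_wgs84 is None or range_geom_wgs84.is_empty:
        return np.empty((0, 2))
    return shapely.get_coordinates(geom_to_cea(range_geom_wgs84))


def _fallback_hull(presence_xy: np.ndarray, range_geom_cea,
                   pixel_km: float, n_points: int) -> AlphaHull:
    """Union of the published range and per-point one-pixel buffers."""
    pieces = []
    if range_geom_cea is not None and not range_geom_cea.is_empty:
        pieces.append(range_geom_cea)
    for x, y in np.asarray(presence_xy, dtype=float).reshape(-1, 2):
        pieces.append(shapely.Point(x, y).buffer(pixel_km * 1000.0))
    geom = unary_union(pieces) if pieces else MultiPolygon([])
    return AlphaHull(geometry=geom, geometry_wgs84=geom_to_wgs84(geom),
                     alpha_km=float("nan"), n_input_points=n_points,
                     fallback_used=True)


def species_hull(presence_xy: np.ndarray,
                 range_geom_wgs84=None,
                 alpha_km: Optional[float] = None,
                 pixel_km: float = 1.0) -> AlphaHull:
    """Build the species' range envelope.

    ``presence_xy``: qualifying presence points in equal-area metres.
    ``range_geom_wgs84``: published-range union (already code-filtered).
    ``alpha_km``: override; by default the median inter-presence distance.

    Hull input is presences ∪ range vertices; the alpha value uses
    presences only.  When the construction is impossible (fewer than three
    non-collinear points, or no usable alpha) the fallback is the union of
    the published range and one-pixel buffers around each presence, with
    ``fallback_used=True``.
    """
    presence_xy = np.asarray(presence_xy, dtype=float).reshape(-1, 2)
    range_cea = None
    if range_geom_wgs84 is not None and not range_geom_wgs84.is_empty:
        range_cea = geom_to_cea(range_geom_wgs84)
    verts = range_vertices(range_geom_wgs84) if range_cea is not None \
        else np.empty((0, 2))
    all_pts = np.vstack([presence_xy, verts])

    if alpha_km is None:
        try:
            alpha_km = median_interpoint_distance(presence_xy)
        except DegenerateInputError:
            return _fallback_hull(presence_xy, range_cea, pixel_km,
                                  len(_distinct(all_pts)))
    try:
        hull = build_alpha_hull(all_pts, alpha_km)
    except DegenerateInputError:
        return _fallback_hull(presence_xy, range_cea, pixel_km,
                              len(_distinct(all_pts)))
    return hull
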