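"""Synthetic landscapes, virtual species and checklist streams.

Every downstream stage of the pipeline is testable offline against these
generators, which carry known ground truth: a species occupies exactly the
pixels inside its true range polygon whose elevation lies in its true band
and whose tree cover meets its true minimum.  A visit to a suitable pixel
detects the species with probability ``detect_prob``; visits elsewhere
never do.

Landscapes are generated directly at 1 km pixels in the project's
cylindrical equal-area CRS, so each pixel is exactly 1 km² and analytic
area checks are exact.  A lon/lat mode exists for projection tests.

Observer effort is either uniform over the landscape or clustered around a
small number of "hotspot" centres with isotropic Gaussian scatter,
mimicking birders' site fidelity.  A configurable fraction of traveling
checklists violates the 7 km / 3 h effort rule, and optional fractions are
historical/incidental, incomplete, unapproved, or dated before 2000, to
exercise every ingest filter.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, box, mapping

from .crs import CEA, WGS84, Affine, cea_to_lonlat, geom_to_wgs84, lonlat_to_cea
from .errors import DegenerateSpeciesError, ParameterError
from .ingest import ChecklistRecord, REDLIST_CATEGORIES
from .raster import Raster, write_raster

DATE_MIN = dt.date(2000, 1, 1)
DATE_MAX = dt.date(2020, 12, 31)

#: Red List category frequencies used when a category is not specified;
#: loosely matches a small-ranged Neotropical forest avifauna (threatened
#: categories over-represented relative to the global list).
CATEGORY_WEIGHTS = {"CR": 0.06, "EN": 0.12, "VU": 0.18, "NT": 0.22, "LC": 0.42}

#: Background species pool so simulated files look like multi-species
#: checklist exports.
BACKGROUND_SPECIES = [f"Background sp{i}" for i in range(1, 6)]


@dataclass
class Landscape:
    """Co-registered elevation and tree-cover grids with georeferencing."""

    elevation: Raster
    cover: Raster
    pixel_km: float

    def __post_init__(self):
        if not self.elevation.aligned_with(self.cover):
            raise ParameterError("elevation/cover grids are not co-registered")
        if self.pixel_km <= 0:
            raise ParameterError("pixel_km must be positive")
        if not np.isfinite(self.elevation.grid).all():
            raise ParameterError("elevation must be finite")
        if self.cover.grid.min() < 0 or self.cover.grid.max() > 100:
            raise ParameterError("cover must lie in [0, 100]")

    @property
    def shape(self):
        return self.elevation.shape

    @property
    def transform(self) -> Affine:
        return self.elevation.transform

    @property
    def crs(self) -> str:
        return self.elevation.crs

    def bbox(self):
        """Shapely box of the full grid extent (landscape CRS)."""
        return box(*self.elevation.bounds())


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def make_landscape(seed: int, shape=(100, 100), elev_model: str = "gradient",
                   forest_fraction: float = 0.5, pixel_km: float = 1.0,
                   origin_lonlat=(-75.0, 5.0), crs: str = CEA) -> Landscape:
    """Generate a deterministic synthetic landscape.

    ``elev_model='gradient'`` ramps elevation 0→3000 m west to east with
    smooth noise; ``'ridge'`` raises a Gaussian mountain ridge along the
    grid's vertical midline.  Tree cover is a smooth random field
    thresholded so that exactly ``forest_fraction`` of pixels are forested
    (cover > 0), with forested covers spread over (0, 100].
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) < 10:
        raise ParameterError("shape must be at least 10×10")
    if not 0.0 < forest_fraction < 1.0:
        raise ParameterError("forest_fraction must be strictly inside (0, 1)")
    if elev_model not in ("gradient", "ridge"):
        raise ParameterError(f"unknown elev_model '{elev_model}'")
    rng = np.random.default_rng(seed)
    nrow, ncol = shape

    noise = _smooth_field(rng, shape, sigma=min(shape) / 12)
    cols = np.linspace(0.0, 1.0, ncol)[None, :]
    if elev_model == "gradient":
        elev = 3000.0 * (0.8 * np.broadcast_to(cols, shape) + 0.2 * noise)
    else:  # ridge
        ridge = np.exp(-0.5 * ((cols - 0.5) / 0.15) ** 2)
        elev = 3000.0 * (0.8 * np.broadcast_to(ridge, shape) + 0.2 * noise)

    field = _smooth_field(rng, shape, sigma=min(shape) / 15)
    cut = np.quantile(field, 1.0 - forest_fraction)
    forested = field > cut
    cover = np.zeros(shape)
    if forested.any():
        # rank-transform the forested field values so cover spreads evenly
        # over (0, 100]: canopy percentages, not raw field amplitudes
        f = field[forested]
        ranks = np.argsort(np.argsort(f)).astype(float)
        denom = max(len(f) - 1, 1)
        cover[forested] = 1.0 + 99.0 * ranks / denom

    if crs == CEA:
        x0, y0 = lonlat_to_cea(*origin_lonlat)
        pix = pixel_km * 1000.0
    elif crs == WGS84:
        x0, y0 = origin_lonlat
        pix = pixel_km / 111.32  # rough degrees-per-km; projection tests only
    else:
        raise ParameterError(f"unknown crs '{crs}'")
    transform = Affine.from_origin(float(x0), float(y0) + nrow * pix, pix, pix)
    return Landscape(
        elevation=Raster(elev, transform, crs),
        cover=Raster(cover, transform, crs),
        pixel_km=pixel_km,
    )


@dataclass
class VirtualSpecies:
    """Ground-truth species definition for recovery tests."""

    species_id: str
    true_range: MultiPolygon          # landscape CRS
    true_range_wgs84: MultiPolygon
    true_elev_min: float
    true_elev_max: float
    true_cover_min: float
    detect_prob: float
    redlist_category: str
    habitat_class: str = "forest"
    documented_elev_min: Optional[float] = None
    documented_elev_max: Optional[float] = None

    def __post_init__(self):
        if not self.true_elev_min < self.true_elev_max:
            raise ParameterError("true elevation band must have min < max")
        if not 0.0 <= self.true_cover_min <= 100.0:
            raise ParameterError("true_cover_min must lie in [0, 100]")
        if not 0.0 < self.detect_prob <= 1.0:
            raise ParameterError("detect_prob must lie in (0, 1]")


def suitability_mask(landscape: Landscape, species: VirtualSpecies) -> np.ndarray:
    """True habitat mask: pixel centre in range ∧ elevation band ∧ cover."""
    import shapely

    xc, yc = landscape.elevation.centers()
    shapely.prepare(species.true_range)
    in_range = shapely.intersects_xy(species.true_range, xc, yc)
    elev = landscape.elevation.grid
    ok = (in_range
          & (elev >= species.true_elev_min)
          & (elev <= species.true_elev_max)
          & (landscape.cover.grid >= species.true_cover_min))
    return ok


def make_species(seed: int, landscape: Landscape, elev_band=(800.0, 2200.0),
                 cover_min: float = 60.0, range_fraction: float = 0.6,
                 detect_prob: float = 0.8, species_id: Optional[str] = None,
                 redlist_category: Optional[str] = None,
                 habitat_class: str = "forest",
                 documented_elev: Optional[tuple] = None) -> VirtualSpecies:
    """Place a virtual species on a landscape.

    The true range is a rectangle covering ``range_fraction`` of the
    landscape bounding box (the full box at fraction 1), positioned
    deterministically from the seed.  Raises
    :class:`DegenerateSpeciesError` when no pixel is suitable.
    """
    if not 0.0 < range_fraction <= 1.0:
        raise ParameterError("range_fraction must lie in (0, 1]")
    elo, ehi = float(elev_band[0]), float(elev_band[1])
    span_lo = float(landscape.elevation.grid.min())
    span_hi = float(landscape.elevation.grid.max())
    if elo < span_lo - 1e-9 or ehi > span_hi + 1e-9:
        raise ParameterError(
            f"elev_band {elev_band} outside landscape span "
            f"({span_lo:.0f}, {span_hi:.0f})")
    rng = np.random.default_rng(seed)
    west, south, east, north = landscape.elevation.bounds()
    w, h = east - west, north - south
    s = np.sqrt(range_fraction)
    rw, rh = w * s, h * s
    if range_fraction == 1.0:
        x0, y0 = west, south
    else:
        x0 = west + rng.uniform(0.0, w - rw)
        y0 = south + rng.uniform(0.0, h - rh)
    rect = box(x0, y0, x0 + rw, y0 + rh)
    true_range = MultiPolygon([rect])
    wgs84 = true_range if landscape.crs == WGS84 else geom_to_wgs84(true_range)

    if redlist_category is None:
        cats = list(CATEGORY_WEIGHTS)
        redlist_category = str(rng.choice(cats, p=[CATEGORY_WEIGHTS[c]
                                                   for c in cats]))
    if species_id is None:
        species_id = f"Virtualis sp{seed}"
    doc_min, doc_max = (documented_elev if documented_elev is not None
                        else (None, None))
    sp = VirtualSpecies(
        species_id=species_id, true_range=true_range, true_range_wgs84=wgs84,
        true_elev_min=elo, true_elev_max=ehi, true_cover_min=float(cover_min),
        detect_prob=float(detect_prob), redlist_category=redlist_category,
        habitat_class=habitat_class,
        documented_elev_min=doc_min, documented_elev_max=doc_max,
    )
    if not suitability_mask(landscape, sp).any():
        raise DegenerateSpeciesError(
            f"no suitable pixel for {species_id} "
            f"(band {elev_band}, cover >= {cover_min})")
    return sp


def _sample_dates(rng, n, pre2000=False):
    if pre2000:
        lo, hi = dt.date(1980, 1, 1), dt.date(1999, 12, 31)
    else:
        lo, hi = DATE_MIN, DATE_MAX
    days = rng.integers(0, (hi - lo).days + 1, size=n)
    return [lo + dt.timedelta(days=int(d)) for d in days]


def simulate_checklists(seed: int, landscape: Landscape,
                        species: VirtualSpecies, n_checklists: int,
                        effort_field: str = "clustered",
                        violation_fraction: float = 0.1,
                        pre2000_fraction: float = 0.0,
                        historical_fraction: float = 0.0,
                        incomplete_fraction: float = 0.0,
                        n_hotspots: int = 8) -> list[ChecklistRecord]:
    """Simulate a stream of complete checklists over the landscape.

    Detection is Bernoulli(``detect_prob``) per visit where the visited
    pixel is truly suitable; non-detection everywhere else.  Exactly
    ``round(n · violation_fraction)`` records violate the traveling effort
    rule (distance above 7 km or duration above 3 h).
    """
    if n_checklists < 1:
        raise ParameterError("n_checklists must be >= 1")
    if effort_field not in ("uniform", "clustered"):
        raise ParameterError(f"unknown effort_field '{effort_field}'")
    rng = np.random.default_rng(seed)
    n = int(n_checklists)
    west, south, east, north = landscape.elevation.bounds()

    # keep sampled positions strictly inside the grid: cell indexing is
    # half-open and the lon/lat round trip costs ~1e-9 m of precision
    margin = 1e-6 * (east - west)
    if effort_field == "uniform":
        xs = rng.uniform(west, east, n)
        ys = rng.uniform(south, north, n)
    else:
        hot = np.column_stack([rng.uniform(west, east, n_hotspots),
                               rng.uniform(south, north, n_hotspots)])
        idx = rng.integers(0, n_hotspots, n)
        sigma = min(east - west, north - south) / 20.0
        xs = hot[idx, 0] + rng.normal(0, sigma, n)
        ys = hot[idx, 1] + rng.normal(0, sigma, n)
    xs = np.clip(xs, west + margin, east - margin)
    ys = np.clip(ys, south + margin, north - margin)

    suitable = suitability_mask(landscape, species)
    row, col = landscape.elevation.rowcol_at(xs, ys)
    at_suitable = (row >= 0) & suitable[np.clip(row, 0, None),
                                        np.clip(col, 0, None)]
    detect = at_suitable & (rng.random(n) < species.detect_prob)

    n_viol = int(round(n * violation_fraction))
    violate = np.zeros(n, dtype=bool)
    violate[rng.choice(n, size=n_viol, replace=False)] = True
    n_pre = int(round(n * pre2000_fraction))
    pre2000 = np.zeros(n, dtype=bool)
    if n_pre:
        pre2000[rng.choice(n, size=n_pre, replace=False)] = True
    histo = rng.random(n) < historical_fraction
    incomplete = rng.random(n) < incomplete_fraction

    if landscape.crs == CEA:
        lons, lats = cea_to_lonlat(xs, ys)
    else:
        lons, lats = xs, ys
    dates_ok = _sample_dates(rng, n)
    dates_pre = _sample_dates(rng, n, pre2000=True)

    records = []
    for i in range(n):
        if histo[i]:
            protocol = "historical" if rng.random() < 0.5 else "incidental"
            distance = float(rng.uniform(0.0, 5.0))
            duration = float(rng.uniform(10.0, 120.0))
        elif violate[i]:
            protocol = "traveling"
            if rng.random() < 0.5:
                distance = float(rng.uniform(7.5, 25.0))   # > 7 km
                duration = float(rng.uniform(30.0, 180.0))
            else:
                distance = float(rng.uniform(0.5, 7.0))
                duration = float(rng.uniform(185.0, 420.0))  # > 3 h
        else:
            if rng.random() < 0.5:
                protocol = "traveling"
                distance = float(rng.uniform(0.1, 7.0))
                duration = float(rng.uniform(10.0, 180.0))
            else:
                protocol = "stationary"
                distance = None
                duration = float(rng.uniform(5.0, 180.0))
        dets = set()
        if detect[i]:
            dets.add(species.species_id)
        for sp in BACKGROUND_SPECIES:
            if rng.random() < 0.3:
                dets.add(sp)
        records.append(ChecklistRecord(
            checklist_id=f"S{seed:04d}-{i:06d}",
            lon=float(lons[i]), lat=float(lats[i]),
            date=dates_pre[i] if pre2000[i] else dates_ok[i],
            protocol=protocol,
            distance_km=distance, duration_min=duration,
            complete=not bool(incomplete[i]), approved=True,
            detections=frozenset(dets),
        ))
    return records


# ---------------------------------------------------------------------------
# file writers (the ingest module's dialect)

def write_landscape(landscape: Landscape, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "elevation": write_raster(landscape.elevation, outdir / "elevation.tif"),
        "cover": write_raster(landscape.cover, outdir / "cover.tif"),
    }


def write_range_geojson(species_list, path) -> Path:
    """Published-range GeoJSON with qualifying P/O/S codes (WGS84)."""
    feats = []
    for sp in (species_list if isinstance(species_list, list) else [species_list]):
        feats.append({
            "type": "Feature",
            "properties": {"species_id": sp.species_id, "presence": 1,
                           "origin": 1, "season": 1},
            "geometry": mapping(sp.true_range_wgs84),
        })
    path = Path(path)
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, sort_keys=True))
    return path


def write_checklists_tsv(records: list[ChecklistRecord], path,
                         columns: Optional[dict] = None) -> Path:
    """One row per detection; empty-species row for empty checklists."""
    from .ingest import DEFAULT_COLUMNS
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    order = ["checklist_id", "species", "lon", "lat", "date", "protocol",
             "distance_km", "duration_min", "complete", "approved"]
    lines = ["\t".join(cols[k] for k in order)]
    for r in records:
        base = {
            "checklist_id": r.checklist_id,
            "lon": f"{r.lon:.8f}", "lat": f"{r.lat:.8f}",
            "date": r.date.isoformat(),
            "protocol": r.protocol,
            "distance_km": "" if r.distance_km is None else f"{r.distance_km:.3f}",
            "duration_min": "" if r.duration_min is None else f"{r.duration_min:.1f}",
            "complete": "1" if r.complete else "0",
            "approved": "1" if r.approved else "0",
        }
        for sp in (sorted(r.detections) or [""]):
            base["species"] = sp
            lines.append("\t".join(base[k] for k in order))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_meta_csv(species_list, path,
                   published_range_km2: Optional[dict] = None) -> Path:
    published_range_km2 = published_range_km2 or {}
    lines = ["species_id,redlist_category,habitat_class,"
             "documented_elev_min,documented_elev_max,published_range_km2"]
    for sp in species_list:
        pub = published_range_km2.get(sp.species_id, "")

        def fmt(v):
            return "" if v is None else f"{v:g}"

        lines.append(",".join([
            sp.species_id, sp.redlist_category, sp.habitat_class,
            fmt(sp.documented_elev_min), fmt(sp.documented_elev_max),
            "" if pub == "" else f"{pub:.6f}",
        ]))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_truth(species_list, path) -> Path:
    """Ground-truth sidecar (JSON key-value) for recovery tests."""
    truth = {}
    for sp in (species_list if isinstance(species_list, list) else [species_list]):
        truth[sp.species_id] = {
            "true_elev_min": sp.true_elev_min,
            "true_elev_max": sp.true_elev_max,
            "true_cover_min": sp.true_cover_min,
            "detect_prob": sp.detect_prob,
            "redlist_category": sp.redlist_category,
            "habitat_class": sp.habitat_class,
            "true_range_wkt": sp.true_range.wkt,
        }
    path = Path(path)
    path.write_text(json.dumps(truth, sort_keys=True, indent=1))
    return path
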