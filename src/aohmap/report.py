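"""Batch orchestration, summary statistics and interactive map export.

Per species the pipeline records the published range area, the Area of
Habitat and its occupied/unoccupied split (all in km² on the equal-area
grid) and the ratio AOH / published range.  Ratios are aggregated per Red
List category into bins below 50%, 50–150% and above 150% of the published
range, plus the fraction of species whose AOH exceeds the published range.
Species with fewer than ten qualifying observations or with open (non
forest) habitat are mapped but excluded from the aggregates.

The interactive HTML maps are self-contained Leaflet documents: every
presence popup carries its checklist id, date, elevation and cover; every
absence square carries its non-detection count; historical/incidental and
external occurrence records are displayed as visually distinct overlay
layers that never enter the computation.
"""

from __future__ import annotations

import base64
import datetime as dt
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping

from .crs import CEA, WGS84, geom_to_cea, lonlat_to_cea
from .errors import (AOHError, DegenerateInputError, ParameterError,
                     SpeciesNotFoundError)
from .habitat import (AOHMask, annotate_presences, compute_aoh,
                      cover_threshold, elevation_limits)
from .hull import AlphaHull, species_hull
from .ingest import (PresenceSet, extract_presences, filter_checklists,
                     read_checklists, read_meta, read_range)
from .occupancy import (AbsenceGrid, OccupancyPartition, build_absence_grid,
                        partition_aoh)
from .raster import Raster, read_raster, write_raster

log = logging.getLogger("aohmap")

RANGE_SCREEN_KM2 = 125_000.0   # species with published ranges at/above this
                               # are outside the method's target set
MIN_OBSERVATIONS = 10          # fewer flags the species as low-confidence


# ---------------------------------------------------------------------------
# areas

def area_km2(obj, crs: Optional[str] = None) -> float:
    """Area in km² of a mask, raster, or polygon in the equal-area CRS.

    Raster/mask areas are pixel count × pixel area.  Geographic (lon/lat)
    geometries are rejected: degrees² is not an area.
    """
    if isinstance(obj, AOHMask):
        return obj.area_km2()
    if isinstance(obj, Raster):
        if obj.crs != CEA:
            raise ParameterError("raster area needs the equal-area CRS")
        return float((obj.grid != 0).sum()) * obj.pixel_area / 1e6
    if isinstance(obj, shapely.Geometry):
        if crs != CEA:
            raise ParameterError(
                "polygon area requires equal-area coordinates; reproject first")
        return float(obj.area) / 1e6
    raise ParameterError(f"cannot compute area of {type(obj).__name__}")


# ---------------------------------------------------------------------------
# per-species summary

FLAGS = ("lt10_obs", "no_qualifying_records", "open_habitat", "fallback_hull")


@dataclass
class SpeciesSummary:
    species_id: str
    redlist_category: str
    published_range_km2: Optional[float]
    aoh_km2: float
    occupied_km2: float
    unoccupied_km2: float
    n_presences: int
    flags: set = field(default_factory=set)

    @property
    def ratio_aoh_range(self) -> Optional[float]:
        if self.published_range_km2 in (None, 0) or \
                not np.isfinite(self.published_range_km2):
            return None
        return self.aoh_km2 / self.published_range_km2


def summarize_species(species_id: str, redlist_category: str,
                      published_range_km2: Optional[float],
                      aoh: Optional[AOHMask],
                      partition: Optional[OccupancyPartition],
                      n_presences: int,
                      flags: Optional[set] = None) -> SpeciesSummary:
    flags = set(flags or ())
    if n_presences < MIN_OBSERVATIONS:
        flags.add("lt10_obs")
    if aoh is None:
        aoh_km2 = occ = unocc = 0.0
    else:
        aoh_km2 = aoh.area_km2()
        pix = aoh.pixel_area_km2()
        if partition is None:
            occ, unocc = aoh_km2, 0.0
        else:
            occ = partition.n_occupied * pix
            unocc = partition.n_unoccupied * pix
    return SpeciesSummary(species_id=species_id,
                          redlist_category=redlist_category,
                          published_range_km2=published_range_km2,
                          aoh_km2=aoh_km2, occupied_km2=occ,
                          unoccupied_km2=unocc,
                          n_presences=n_presences, flags=flags)


# ---------------------------------------------------------------------------
# category aggregates

@dataclass
class CategoryTable:
    """Per-category ratio-bin fractions (and counts)."""

    table: pd.DataFrame            # index: category; columns below
    bins: tuple

    COLUMNS = ("n", "frac_lt_low", "frac_mid", "frac_gt_high", "frac_gt_100")


def category_table(summaries: list[SpeciesSummary],
                   bins=(0.5, 1.5)) -> CategoryTable:
    """Bin per-species AOH/range ratios by Red List category.

    Species flagged ``lt10_obs`` or ``open_habitat`` and species without a
    known published range are excluded from the aggregate.
    """
    lo, hi = bins
    usable = [s for s in summaries
              if s.ratio_aoh_range is not None
              and not ({"lt10_obs", "open_habitat",
                        "no_qualifying_records"} & s.flags)]
    if not usable:
        raise ParameterError("no usable summaries for the category table")
    rows = {}
    for cat in ("CR", "EN", "VU", "NT", "LC"):
        ratios = np.array([s.ratio_aoh_range for s in usable
                           if s.redlist_category == cat])
        if ratios.size == 0:
            continue
        n = ratios.size
        rows[cat] = {
            "n": n,
            "frac_lt_low": float((ratios < lo).sum()) / n,
            "frac_mid": float(((ratios >= lo) & (ratios <= hi)).sum()) / n,
            "frac_gt_high": float((ratios > hi).sum()) / n,
            "frac_gt_100": float((ratios > 1.0).sum()) / n,
        }
    return CategoryTable(table=pd.DataFrame.from_dict(rows, orient="index"),
                         bins=tuple(bins))


# ---------------------------------------------------------------------------
# interactive map

_LEAFLET_CSS = "https://unpkg.com/leaflet@1.9.4/dist/leaflet.css"
_LEAFLET_JS = "https://unpkg.com/leaflet@1.9.4/dist/leaflet.js"

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"/>
<title>{title}</title>
<link rel="stylesheet" href="{css}"/>
<script src="{js}"></script>
<style>html,body,#map{{height:100%;margin:0}}</style>
</head><body><div id="map"></div>
<script>
var map = L.map('map');
var overlays = {{}};
{layers}
L.control.layers(null, overlays).addTo(map);
map.fitBounds({bounds});
</script></body></html>
"""


def _partition_png(partition: OccupancyPartition) -> str:
    """Base64 PNG of the partition (green occupied, brown unoccupied)."""
    from PIL import Image

    rgba = np.zeros(partition.grid.shape + (4,), dtype=np.uint8)
    rgba[partition.grid == 1] = (34, 139, 34, 180)    # occupied: green
    rgba[partition.grid == 2] = (139, 90, 43, 180)    # unoccupied: brown
    buf = io.BytesIO()
    Image.fromarray(rgba).save(buf, format="PNG")
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _grid_lonlat_bounds(transform, shape, crs):
    from .crs import cea_to_lonlat

    nrow, ncol = shape
    x0, y0 = transform * (0, 0)
    x1, y1 = transform * (ncol, nrow)
    if crs == CEA:
        lon0, lat0 = cea_to_lonlat(x0, y0)
        lon1, lat1 = cea_to_lonlat(x1, y1)
    else:
        lon0, lat0, lon1, lat1 = x0, y0, x1, y1
    south, north = sorted([float(lat0), float(lat1)])
    west, east = sorted([float(lon0), float(lon1)])
    return south, west, north, east


def _geojson_layer(name, geom_wgs84, style):
    gj = json.dumps(mapping(geom_wgs84))
    return (f"overlays[{name!r}] = L.geoJSON({gj}, {{style: function() "
            f"{{return {json.dumps(style)};}}}}).addTo(map);")


def _point_layer(name, points, color, popups, radius=5):
    markers = []
    for (lon, lat), pop in zip(points, popups):
        markers.append(
            f"L.circleMarker([{lat:.6f},{lon:.6f}],"
            f"{{radius:{radius},color:{color!r},fillOpacity:0.8}})"
            f".bindPopup({json.dumps(pop)})")
    return (f"overlays[{name!r}] = L.layerGroup(["
            + ",".join(markers) + "]).addTo(map);")


def export_map(path, species_id: str,
               hull: Optional[AlphaHull] = None,
               partition: Optional[OccupancyPartition] = None,
               presences: Optional[PresenceSet] = None,
               absences: Optional[AbsenceGrid] = None,
               published_range=None,
               overlay_points: Optional[list] = None) -> Path:
    """Write a self-contained interactive HTML map.

    ``overlay_points`` are (lon, lat, label) display-only records
    (historical/incidental checklists, external databases); they are drawn
    in a distinct colour and never used in any computation.  Raises
    :class:`ParameterError` when every layer is empty.
    """
    layers = []
    bounds = None

    if published_range is not None and not published_range.is_empty:
        layers.append(_geojson_layer("Published range", published_range,
                                     {"color": "#e08214", "weight": 2,
                                      "fillOpacity": 0.05}))
    if hull is not None and not hull.geometry_wgs84.is_empty:
        layers.append(_geojson_layer("Alpha hull", hull.geometry_wgs84,
                                     {"color": "#2166ac", "weight": 2,
                                      "fillOpacity": 0.05}))
    if partition is not None and (partition.grid > 0).any():
        south, west, north, east = _grid_lonlat_bounds(
            partition.transform, partition.grid.shape, partition.crs)
        png = _partition_png(partition)
        layers.append(
            f"overlays['Area of Habitat'] = L.imageOverlay("
            f"'data:image/png;base64,{png}',"
            f"[[{south},{west}],[{north},{east}]],{{opacity:0.8}}).addTo(map);")
        bounds = [[south, west], [north, east]]
    if presences is not None and len(presences):
        pts = [(p.lon, p.lat) for p in presences.points]
        pops = [
            f"Checklist {p.checklist_id}<br>Date: {p.date.isoformat()}<br>"
            f"Elevation: {'' if p.elevation is None else round(p.elevation)} m"
            f"<br>Tree cover: {'' if p.cover is None else round(p.cover)} %"
            for p in presences.points]
        layers.append(_point_layer("Presences", pts, "#d6604d", pops))
    if absences is not None and len(absences):
        half_deg = absences.cell_km / 222.64  # half cell, rough degrees
        squares = []
        for c in absences.cells:
            lon, lat = c.centroid_lonlat
            pop = f"Absence cell: {c.n_checklists} non-detection checklists"
            squares.append(
                f"L.rectangle([[{lat - half_deg},{lon - half_deg}],"
                f"[{lat + half_deg},{lon + half_deg}]],"
                f"{{color:'#4393c3',weight:1}})"
                f".bindPopup({json.dumps(pop)})")
        layers.append("overlays['Inferred absences'] = L.layerGroup(["
                      + ",".join(squares) + "]).addTo(map);")
    if overlay_points:
        pts = [(lon, lat) for lon, lat, _ in overlay_points]
        pops = [f"{label} (display only; excluded from analysis)"
                for _, _, label in overlay_points]
        layers.append(_point_layer("Unvetted records (display only)", pts,
                                   "#000000", pops, radius=4))

    if not layers:
        raise ParameterError("no nonempty layers to map")
    if bounds is None:
        lats = [p.lat for p in (presences.points if presences else [])] or [0.0]
        lons = [p.lon for p in (presences.points if presences else [])] or [0.0]
        bounds = [[min(lats) - 0.1, min(lons) - 0.1],
                  [max(lats) + 0.1, max(lons) + 0.1]]
    html = _HTML_TEMPLATE.format(title=f"Area of Habitat — {species_id}",
                                 css=_LEAFLET_CSS, js=_LEAFLET_JS,
                                 layers="\n".join(layers),
                                 bounds=json.dumps(bounds))
    path = Path(path)
    path.write_text(html)
    return path


# ---------------------------------------------------------------------------
# batch driver

@dataclass
class BatchConfig:
    checklists: Path
    ranges: Path
    meta: Path
    elevation: Path
    cover: Path
    out_dir: Path
    species: Optional[list] = None
    date_floor: dt.date = dt.date(2000, 1, 1)
    cell_km: float = 5.0
    min_checklists: int = 25
    range_screen_km2: float = RANGE_SCREEN_KM2
    screen_large_ranges: bool = True
    ratio_bins: tuple = (0.5, 1.5)
    write_maps: bool = True
    write_rasters: bool = True

    @classmethod
    def from_file(cls, path) -> "BatchConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except Exception as exc:
            raise ParameterError(f"unreadable config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ParameterError(f"config {path} is not a key-value mapping")
        paths = raw.get("paths", {})
        params = raw.get("params", {})
        kwargs = {}
        for key in ("checklists", "ranges", "meta", "elevation", "cover"):
            if key not in paths:
                raise ParameterError(f"config lacks paths.{key}")
            kwargs[key] = Path(paths[key])
        kwargs["out_dir"] = Path(raw.get("out", "aoh_out"))
        kwargs["species"] = raw.get("species")
        if "date_floor" in params:
            kwargs["date_floor"] = dt.date.fromisoformat(str(params["date_floor"]))
        for key in ("cell_km", "min_checklists", "range_screen_km2"):
            if key in params:
                kwargs[key] = params[key]
        if "screen_large_ranges" in params:
            kwargs["screen_large_ranges"] = bool(params["screen_large_ranges"])
        if "ratio_bins" in params:
            kwargs["ratio_bins"] = tuple(params["ratio_bins"])
        if "write_maps" in params:
            kwargs["write_maps"] = bool(params["write_maps"])
        if "write_rasters" in params:
            kwargs["write_rasters"] = bool(params["write_rasters"])
        return cls(**kwargs)


@dataclass
class BatchResult:
    summaries: list
    exclusions: list               # (species_id, reason)
    category: Optional[CategoryTable]
    out_dir: Path


def _summary_frame(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    rows = []
    for s in sorted(summaries, key=lambda s: s.species_id):
        rows.append({
            "species_id": s.species_id,
            "redlist_category": s.redlist_category,
            "published_range_km2": s.published_range_km2,
            "aoh_km2": round(s.aoh_km2, 6),
            "occupied_km2": round(s.occupied_km2, 6),
            "unoccupied_km2": round(s.unoccupied_km2, 6),
            "ratio_aoh_range": ("" if s.ratio_aoh_range is None
                                else round(s.ratio_aoh_range, 6)),
            "n_presences": s.n_presences,
            "flags": ";".join(sorted(s.flags)),
        })
    return pd.DataFrame(rows)


def process_species(species_id: str, records, meta, range_path,
                    elevation: Raster, cover: Raster,
                    cfg: BatchConfig):
    """Run every pipeline stage for one species.

    Returns (summary, artifacts dict) or raises for unrecoverable input
    problems; the batch driver logs and continues.
    """
    flags: set = set()
    presences = extract_presences(records, species_id,
                                  min_date=cfg.date_floor)
    log.info("%s: %d qualifying presences", species_id, len(presences))
    if presences.no_qualifying_records:
        return None, {"reason": "no_qualifying_records"}

    try:
        published = read_range(range_path, species_id).geometry
    except SpeciesNotFoundError:
        published = None
    pub_km2 = (meta.published_range_km2 if meta and
               meta.published_range_km2 is not None
               else (area_km2(geom_to_cea(published), CEA)
                     if published is not None else None))

    ll = presences.lonlat("hull")
    px, py = lonlat_to_cea(ll[:, 0], ll[:, 1])
    pres_xy = np.column_stack([px, py])
    hull = species_hull(pres_xy, published,
                        pixel_km=elevation.pixel_width / 1000.0)
    if hull.fallback_used:
        flags.add("fallback_hull")

    annotate_presences(presences, elevation, cover)
    limits = elevation_limits(presences, meta)
    mode = "forest"
    threshold = None
    if meta is not None and meta.habitat_class == "open":
        mode = "elevation_only"
        flags.add("open_habitat")
    else:
        try:
            threshold = cover_threshold(presences)
        except DegenerateInputError:
            mode = "elevation_only"
            flags.add("open_habitat")
    aoh = compute_aoh(hull.geometry, elevation, cover, limits, threshold,
                      mode=mode)
    log.info("%s: AOH %d pixels (%s mode)", species_id, aoh.n_pixels, mode)

    absences = build_absence_grid(records, species_id, aoh,
                                  cell_km=cfg.cell_km,
                                  min_checklists=cfg.min_checklists)
    partition = (partition_aoh(aoh, presences, absences)
                 if aoh.n_pixels else None)
    summary = summarize_species(
        species_id, meta.redlist_category if meta else "LC", pub_km2,
        aoh, partition, n_presences=len(presences), flags=flags)
    artifacts = {"presences": presences, "hull": hull, "limits": limits,
                 "threshold": threshold, "aoh": aoh, "absences": absences,
                 "partition": partition, "published": published}
    return summary, artifacts


def run_batch(config) -> BatchResult:
    """Run the full batch described by a config mapping or YAML file path.

    Deterministic for identical inputs: species are processed in sorted
    order and all CSV values use fixed formatting, so a rerun produces
    byte-identical outputs.
    """
    cfg = config if isinstance(config, BatchConfig) \
        else BatchConfig.from_file(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = filter_checklists(read_checklists(cfg.checklists))
    meta_map = read_meta(cfg.meta)
    elevation = read_raster(cfg.elevation)
    cover = read_raster(cfg.cover)
    species = sorted(cfg.species or meta_map)

    summaries, exclusions = [], []
    for sid in species:
        meta = meta_map.get(sid)
        if (cfg.screen_large_ranges and meta is not None
                and meta.published_range_km2 is not None
                and meta.published_range_km2 >= cfg.range_screen_km2):
            exclusions.append((sid, "range_above_threshold"))
            continue
        try:
            summary, artifacts = process_species(
                sid, records, meta, cfg.ranges, elevation, cover, cfg)
        except AOHError as exc:
            log.warning("%s failed: %s", sid, exc)
            exclusions.append((sid, f"error:{type(exc).__name__}"))
            continue
        if summary is None:
            exclusions.append((sid, artifacts["reason"]))
            continue
        summaries.append(summary)
        safe = sid.replace(" ", "_")
        if cfg.write_rasters and artifacts["aoh"] is not None:
            write_raster(artifacts["aoh"].as_raster(), out / f"{safe}_aoh.tif")
            if artifacts["partition"] is not None:
                write_raster(Raster(artifacts["partition"].grid,
                                    artifacts["partition"].transform,
                                    artifacts["partition"].crs),
                             out / f"{safe}_partition.tif")
        hull_gj = {
            "type": "Feature",
            "properties": {
                "species_id": sid,
                "alpha_km": (None if not np.isfinite(artifacts["hull"].alpha_km)
                             else round(artifacts["hull"].alpha_km, 6)),
                "n_input_points": artifacts["hull"].n_input_points,
                "fallback_used": artifacts["hull"].fallback_used,
            },
            "geometry": mapping(artifacts["hull"].geometry_wgs84),
        }
        (out / f"{safe}_hull.geojson").write_text(
            json.dumps(hull_gj, sort_keys=True))
        abs_gj = {"type": "FeatureCollection", "features": [
            {"type": "Feature",
             "properties": {"n_checklists": c.n_checklists},
             "geometry": {"type": "Point",
                          "coordinates": [round(c.centroid_lonlat[0], 8),
                                          round(c.centroid_lonlat[1], 8)]}}
            for c in artifacts["absences"].cells]}
        (out / f"{safe}_absences.geojson").write_text(
            json.dumps(abs_gj, sort_keys=True))
        if cfg.write_maps:
            try:
                export_map(out / f"{safe}_map.html", sid,
                           hull=artifacts["hull"],
                           partition=artifacts["partition"],
                           presences=artifacts["presences"],
                           absences=artifacts["absences"],
                           published_range=artifacts["published"])
            except ParameterError:
                pass

    _summary_frame(summaries).to_csv(out / "species_summary.csv", index=False)
    pd.DataFrame(exclusions, columns=["species_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False)
    cat = None
    try:
        cat = category_table(summaries, bins=cfg.ratio_bins)
        cat.table.to_csv(out / "category_table.csv",
                         index_label="redlist_category")
    except ParameterError:
        pass
    return BatchResult(summaries=summaries, exclusions=exclusions,
                       category=cat, out_dir=out)
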