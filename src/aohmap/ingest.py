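"""Reading and quality-filtering of the pipeline's inputs.

Checklists arrive in an eBird-Basic-Dataset-like tab-separated layout (one
row per observation; a row with an empty species field represents a complete
checklist that detected nothing).  Published ranges arrive as GeoJSON with
per-polygon Presence/Origin/Season codes; species metadata as CSV.

The qualification rules applied here: keep only approved, complete
checklists; drop Historical and Incidental protocols; drop traveling
checklists whose distance exceeds 7 km or whose duration exceeds 3 hours
(thresholds inclusive — strictly "above" is excluded).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape
from shapely.ops import unary_union

from .errors import (FormatError, SpeciesNotFoundError, ValidationError)

# ---------------------------------------------------------------------------
# dialect

#: Default TSV column names (EBD-like); override via the ``columns`` mapping.
DEFAULT_COLUMNS = {
    "checklist_id": "SAMPLING EVENT IDENTIFIER",
    "species": "SCIENTIFIC NAME",
    "lon": "LONGITUDE",
    "lat": "LATITUDE",
    "date": "OBSERVATION DATE",
    "protocol": "PROTOCOL TYPE",
    "distance_km": "EFFORT DISTANCE KM",
    "duration_min": "DURATION MINUTES",
    "complete": "ALL SPECIES REPORTED",
    "approved": "APPROVED",
}

PROTOCOLS = ("stationary", "traveling", "historical", "incidental", "other")

MAX_TRAVEL_KM = 7.0       # traveling checklists above this are excluded
MAX_DURATION_MIN = 180.0  # ... or longer than 3 hours


def _normalize_protocol(raw: str) -> str:
    p = str(raw).strip().lower()
    return p if p in PROTOCOLS else "other"


@dataclass(frozen=True)
class ChecklistRecord:
    """One effort-qualified survey event with its species detections."""

    checklist_id: str
    lon: float
    lat: float
    date: dt.date
    protocol: str
    distance_km: Optional[float]
    duration_min: Optional[float]
    complete: bool
    approved: bool
    detections: frozenset = field(default_factory=frozenset)

    def detects(self, species_id: str) -> bool:
        return species_id in self.detections


# ---------------------------------------------------------------------------
# checklist reading

def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    return s in ("1", "true", "t", "yes", "y")


def _parse_effort(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
        return None
    return float(v)


def read_checklists(path, columns: Optional[dict] = None) -> list[ChecklistRecord]:
    """Read a checklist TSV, grouping observation rows into records.

    Raises :class:`FormatError` naming the first missing mandatory column,
    and :class:`ValidationError` for rows with out-of-range coordinates or
    negative effort values.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"checklist file lacks mandatory column "
                              f"'{name}' (role: {key})")

    records: dict[str, ChecklistRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        cid = row[cols["checklist_id"]].strip()
        lon = float(row[cols["lon"]])
        lat = float(row[cols["lat"]])
        if not (-90.0 <= lat <= 90.0):
            raise ValidationError(f"row {i}: latitude {lat} outside [-90, 90]")
        if not (-180.0 <= lon <= 180.0):
            raise ValidationError(f"row {i}: longitude {lon} outside [-180, 180]")
        distance = _parse_effort(row[cols["distance_km"]])
        duration = _parse_effort(row[cols["duration_min"]])
        if (distance is not None and distance < 0) or \
           (duration is not None and duration < 0):
            raise ValidationError(f"row {i}: negative effort value")
        species = row[cols["species"]].strip()
        detections = frozenset([species]) if species else frozenset()
        rec = ChecklistRecord(
            checklist_id=cid,
            lon=lon,
            lat=lat,
            date=dt.date.fromisoformat(row[cols["date"]].strip()),
            protocol=_normalize_protocol(row[cols["protocol"]]),
            distance_km=distance,
            duration_min=duration,
            complete=_parse_bool(row[cols["complete"]]),
            approved=_parse_bool(row[cols["approved"]]),
            detections=detections,
        )
        if cid in records:  # merge further observation rows of the checklist
            prev = records[cid]
            records[cid] = replace(prev, detections=prev.detections | detections)
        else:
            records[cid] = rec
    return list(records.values())


# ---------------------------------------------------------------------------
# effort filter

def record_qualifies(rec: ChecklistRecord) -> bool:
    """Apply the checklist qualification rules to a single record."""
    if not (rec.approved and rec.complete):
        return False
    if rec.protocol in ("historical", "incidental"):
        return False
    if rec.protocol == "traveling":
        # a traveling list without a recorded distance cannot be verified
        # against the 7 km rule, so it is excluded (conservative choice)
        if rec.distance_km is None:
            return False
        if rec.distance_km > MAX_TRAVEL_KM:
            return False
        if rec.duration_min is not None and rec.duration_min > MAX_DURATION_MIN:
            return False
    return True


def filter_checklists(records: Iterable[ChecklistRecord]) -> list[ChecklistRecord]:
    """Keep qualifying records, preserving input order (idempotent)."""
    return [r for r in records if record_qualifies(r)]


# ---------------------------------------------------------------------------
# presences

@dataclass
class PresencePoint:
    """One qualifying detection, with provenance and (later) annotations."""

    checklist_id: str
    lon: float
    lat: float
    date: dt.date
    elevation: Optional[float] = None
    cover: Optional[float] = None


@dataclass
class PresenceSet:
    """Qualifying presence points for one species.

    ``points`` holds every qualifying detection (used for hull building and
    occupancy); :meth:`habitat_points` restricts to the date floor used for
    elevation/cover extraction.
    """

    species_id: str
    points: list[PresencePoint]
    date_floor: dt.date = dt.date(2000, 1, 1)

    @property
    def no_qualifying_records(self) -> bool:
        return len(self.points) == 0

    def __len__(self) -> int:
        return len(self.points)

    def hull_points(self) -> list[PresencePoint]:
        return list(self.points)

    def habitat_points(self) -> list[PresencePoint]:
        return [p for p in self.points if p.date >= self.date_floor]

    def lonlat(self, subset: str = "hull") -> np.ndarray:
        pts = self.hull_points() if subset == "hull" else self.habitat_points()
        if not pts:
            return np.empty((0, 2))
        return np.array([[p.lon, p.lat] for p in pts])


def extract_presences(records: Iterable[ChecklistRecord], species_id: str,
                      min_date: dt.date = dt.date(2000, 1, 1)) -> PresenceSet:
    """One presence point per qualifying record detecting ``species_id``.

    Duplicate checklist ids are collapsed to a single point.  An empty
    result is returned as a valid (flagged) set; the batch driver records
    the species as excluded.
    """
    if not species_id:
        raise ValidationError("species_id must be non-empty")
    seen: set[str] = set()
    points = []
    for rec in records:
        if rec.detects(species_id) and rec.checklist_id not in seen:
            seen.add(rec.checklist_id)
            points.append(PresencePoint(rec.checklist_id, rec.lon, rec.lat,
                                        rec.date))
    return PresenceSet(species_id=species_id, points=points,
                       date_floor=min_date)


# ---------------------------------------------------------------------------
# published ranges

#: Polygon code rule: Presence 1 (extant), Origin 1 or 2 (native or
#: reintroduced), Season 1 or 2 (resident or breeding).
KEEP_PRESENCE = (1,)
KEEP_ORIGIN = (1, 2)
KEEP_SEASON = (1, 2)


@dataclass
class PublishedRange:
    """Code-filtered published range polygons for one species (WGS84)."""

    species_id: str
    polygons: list  # (geometry, presence, origin, season) tuples that qualify
    n_dropped: int = 0

    @property
    def geometry(self):
        """Union of the qualifying polygons (empty if none qualify)."""
        if not self.polygons:
            return shapely.MultiPolygon([])
        return unary_union([g for g, *_ in self.polygons])


def _repair(geom):
    if not geom.is_valid:
        geom = geom.buffer(0)  # zero-width buffer repair convention
    return geom


def read_range(path, species_id: str) -> PublishedRange:
    """Read a GeoJSON range file and keep the qualifying polygons.

    Features need properties ``species_id``, ``presence``, ``origin`` and
    ``season``.  Invalid geometries are repaired with a zero-width buffer.
    """
    gj = json.loads(Path(path).read_text())
    feats = [f for f in gj.get("features", [])
             if f.get("properties", {}).get("species_id") == species_id]
    if not feats:
        raise SpeciesNotFoundError(f"species '{species_id}' not in {path}")
    kept, dropped = [], 0
    for f in feats:
        p = f["properties"]
        codes = (int(p.get("presence", 1)), int(p.get("origin", 1)),
                 int(p.get("season", 1)))
        if codes[0] in KEEP_PRESENCE and codes[1] in KEEP_ORIGIN \
                and codes[2] in KEEP_SEASON:
            kept.append((_repair(geojson_shape(f["geometry"])), *codes))
        else:
            dropped += 1
    return PublishedRange(species_id=species_id, polygons=kept,
                          n_dropped=dropped)


# ---------------------------------------------------------------------------
# species metadata

REDLIST_CATEGORIES = ("CR", "EN", "VU", "NT", "LC")
HABITAT_CLASSES = ("forest", "open")


@dataclass
class SpeciesMeta:
    """Red List category, documented elevations and habitat class."""

    species_id: str
    redlist_category: str
    habitat_class: str = "forest"
    documented_elev_min: Optional[float] = None
    documented_elev_max: Optional[float] = None
    published_range_km2: Optional[float] = None

    def __post_init__(self):
        if self.redlist_category not in REDLIST_CATEGORIES:
            raise ValidationError(
                f"unknown Red List category '{self.redlist_category}'")
        if self.habitat_class not in HABITAT_CLASSES:
            raise ValidationError(f"unknown habitat class '{self.habitat_class}'")
        if (self.documented_elev_min is not None
                and self.documented_elev_max is not None
                and self.documented_elev_min > self.documented_elev_max):
            raise ValidationError("documented elevation min > max")


def read_meta(path) -> dict[str, SpeciesMeta]:
    """Read the species metadata CSV into a dict keyed by species id."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise FormatError("metadata file lacks mandatory column 'species_id'")
    out = {}
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) \
                else float(v)

        meta = SpeciesMeta(
            species_id=str(d["species_id"]),
            redlist_category=str(d["redlist_category"]),
            habitat_class=str(d.get("habitat_class", "forest")),
            documented_elev_min=opt("documented_elev_min"),
            documented_elev_max=opt("documented_elev_max"),
            published_range_km2=opt("published_range_km2"),
        )
        out[meta.species_id] = meta
    return out
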