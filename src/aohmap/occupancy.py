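"""Inferred absences and the occupied/unoccupied partition of the AOH.

An absence cell is a 5 km × 5 km grid cell surveyed by at least 25
qualifying complete checklists, none of which detected the focal species.
Only checklists whose location falls on an AOH pixel count towards the
threshold (a checklist in unsuitable habitat says nothing about absence),
but a detection anywhere in the cell disqualifies it, because presences are
honoured even outside the AOH.

The AOH is then split by a plain nearest-neighbour rule: each AOH pixel is
Potentially Occupied if the nearest point among presences and absence-cell
centroids (projected Euclidean distance from the pixel centre) is a
presence, Potentially Unoccupied otherwise.  Exact ties label occupied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .crs import CEA, cea_to_lonlat, lonlat_to_cea
from .errors import EmptyPartitionError, ParameterError
from .habitat import AOHMask
from .ingest import ChecklistRecord, PresenceSet

DEFAULT_CELL_KM = 5.0
DEFAULT_MIN_CHECKLISTS = 25


@dataclass
class AbsenceCell:
    """One qualifying absence cell (indices on the 5 km grid)."""

    cell_index: tuple          # (cell_row, cell_col) from the raster origin
    n_checklists: int          # AOH-pixel non-detection checklists
    centroid_xy: tuple         # equal-area metres
    centroid_lonlat: tuple

    @property
    def count(self) -> int:
        return self.n_checklists


@dataclass
class AbsenceGrid:
    """All inferred-absence cells for one species."""

    cell_km: float = DEFAULT_CELL_KM
    min_checklists: int = DEFAULT_MIN_CHECKLISTS
    cells: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def centroids_xy(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 2))
        return np.array([c.centroid_xy for c in self.cells])


def build_absence_grid(checklists: list[ChecklistRecord], species_id: str,
                       aoh: AOHMask,
                       cell_km: float = DEFAULT_CELL_KM,
                       min_checklists: int = DEFAULT_MIN_CHECKLISTS) -> AbsenceGrid:
    """Aggregate qualifying checklists into inferred-absence cells.

    ``checklists`` must already have passed the ingest effort filter.  The
    aggregation grid is anchored at the AOH raster origin (upper-left
    corner) and indexed like the raster (rows increase southwards).
    """
    if cell_km <= 0 or min_checklists < 1:
        raise ParameterError("cell_km must be > 0 and min_checklists >= 1")
    grid = AbsenceGrid(cell_km=cell_km, min_checklists=min_checklists)
    if not checklists:
        return grid
    cell_m = cell_km * 1000.0
    t = aoh.transform
    x0, y0 = t.c, t.f  # raster origin (upper-left corner)

    lon = np.array([r.lon for r in checklists])
    lat = np.array([r.lat for r in checklists])
    if aoh.crs == CEA:
        x, y = lonlat_to_cea(lon, lat)
    else:
        x, y = lon, lat
    crow = np.floor((y0 - y) / cell_m).astype(int)
    ccol = np.floor((x - x0) / cell_m).astype(int)

    # is each checklist located on an AOH pixel?
    col_f = (x - t.c) / t.a
    row_f = (y - t.f) / t.e
    prow = np.floor(row_f).astype(int)
    pcol = np.floor(col_f).astype(int)
    ingrid = ((prow >= 0) & (prow < aoh.shape[0])
              & (pcol >= 0) & (pcol < aoh.shape[1]))
    on_aoh = np.zeros(len(checklists), dtype=bool)
    on_aoh[ingrid] = aoh.grid[prow[ingrid], pcol[ingrid]]

    counts: dict[tuple, int] = {}
    detected: set[tuple] = set()
    for i, rec in enumerate(checklists):
        key = (int(crow[i]), int(ccol[i]))
        if rec.detects(species_id):
            detected.add(key)        # any in-cell detection disqualifies
        elif on_aoh[i]:
            counts[key] = counts.get(key, 0) + 1

    for key in sorted(counts):
        if key in detected or counts[key] < min_checklists:
            continue
        cr, cc = key
        cx = x0 + (cc + 0.5) * cell_m
        cy = y0 - (cr + 0.5) * cell_m
        lonc, latc = (cea_to_lonlat(cx, cy) if aoh.crs == CEA else (cx, cy))
        grid.cells.append(AbsenceCell(cell_index=key,
                                      n_checklists=counts[key],
                                      centroid_xy=(float(cx), float(cy)),
                                      centroid_lonlat=(float(lonc), float(latc))))
    return grid


OUTSIDE, OCCUPIED, UNOCCUPIED = 0, 1, 2


@dataclass
class OccupancyPartition:
    """Ternary per-pixel labelling of the AOH grid."""

    grid: np.ndarray           # uint8: 0 outside, 1 occupied, 2 unoccupied
    transform: "object"
    crs: str

    @property
    def n_occupied(self) -> int:
        return int((self.grid == OCCUPIED).sum())

    @property
    def n_unoccupied(self) -> int:
        return int((self.grid == UNOCCUPIED).sum())


def partition_aoh(aoh: AOHMask, presences: PresenceSet | np.ndarray,
                  absences: AbsenceGrid) -> OccupancyPartition:
    """Nearest-neighbour partition of the AOH into occupied/unoccupied.

    ``presences`` may be a PresenceSet (points projected internally) or an
    (n, 2) array already in the AOH's CRS.  With no absence cells every AOH
    pixel is occupied; with no presences every AOH pixel is unoccupied;
    with neither the partition is undefined and an error is raised.
    """
    if isinstance(presences, PresenceSet):
        ll = presences.lonlat("hull")
        if aoh.crs == CEA and len(ll):
            px, py = lonlat_to_cea(ll[:, 0], ll[:, 1])
            pres_xy = np.column_stack([px, py])
        else:
            pres_xy = ll
    else:
        pres_xy = np.asarray(presences, dtype=float).reshape(-1, 2)
    abs_xy = absences.centroids_xy()

    if len(pres_xy) == 0 and len(abs_xy) == 0:
        raise EmptyPartitionError("no presences and no absence cells")

    labels = np.zeros(aoh.shape, dtype=np.uint8)
    sel = aoh.grid
    if len(abs_xy) == 0:
        labels[sel] = OCCUPIED
    elif len(pres_xy) == 0:
        labels[sel] = UNOCCUPIED
    else:
        xc, yc = aoh.as_raster().centers()
        pts = np.column_stack([xc[sel], yc[sel]])
        d_pres, _ = cKDTree(pres_xy).query(pts)
        d_abs, _ = cKDTree(abs_xy).query(pts)
        occ = d_pres <= d_abs  # tie labels occupied
        lab = np.where(occ, OCCUPIED, UNOCCUPIED).astype(np.uint8)
        labels[sel] = lab
    return OccupancyPartition(grid=labels, transform=aoh.transform,
                              crs=aoh.crs)
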