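"""Shared fixtures: small synthetic landscapes, species, checklist streams."""

import datetime as dt

import numpy as np
import pytest

from aohmap import fixtures as fx
from aohmap.crs import CEA, Affine
from aohmap.habitat import AOHMask
from aohmap.ingest import ChecklistRecord
from aohmap.raster import Raster


@pytest.fixture(scope="session")
def landscape():
    """100×100 gradient landscape at exact 1 km² pixels, half forested."""
    return fx.make_landscape(seed=1, shape=(100, 100), elev_model="gradient",
                             forest_fraction=0.5)


@pytest.fixture(scope="session")
def species(landscape):
    return fx.make_species(seed=2, landscape=landscape,
                           elev_band=(600.0, 2400.0), cover_min=40.0,
                           range_fraction=0.7, detect_prob=0.9)


@pytest.fixture(scope="session")
def records(landscape, species):
    return fx.simulate_checklists(seed=3, landscape=landscape,
                                  species=species, n_checklists=2000,
                                  effort_field="clustered",
                                  violation_fraction=0.1)


def make_record(cid="C1", lon=0.0, lat=0.0, date=dt.date(2010, 6, 1),
                protocol="stationary", distance_km=None, duration_min=60.0,
                complete=True, approved=True, detections=()):
    """Hand-built checklist record with sensible defaults."""
    return ChecklistRecord(checklist_id=cid, lon=lon, lat=lat, date=date,
                           protocol=protocol, distance_km=distance_km,
                           duration_min=duration_min, complete=complete,
                           approved=approved,
                           detections=frozenset(detections))


def flat_aoh(shape=(40, 40), origin=(0.0, 0.0), pixel_m=1000.0,
             mask=None, mode="forest"):
    """AOH mask on a simple equal-area grid anchored at ``origin``."""
    transform = Affine.from_origin(origin[0],
                                   origin[1] + shape[0] * pixel_m,
                                   pixel_m, pixel_m)
    grid = np.ones(shape, dtype=bool) if mask is None else mask
    return AOHMask(grid=grid, transform=transform, crs=CEA, mode=mode)
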