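"""Areas, summaries, category aggregates, HTML maps and the batch driver."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from aohmap import fixtures as fx
from aohmap.crs import CEA, WGS84
from aohmap.errors import ParameterError
from aohmap.report import (BatchConfig, SpeciesSummary, area_km2,
                           category_table, export_map, run_batch,
                           summarize_species)

from conftest import flat_aoh


class TestAreaKm2:
    def test_pixel_count_on_exact_grid(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask.flat[:100] = True
        assert area_km2(flat_aoh(shape=(20, 20), mask=mask)) == 100.0

    def test_analytic_rectangle(self):
        rect = box(0.0, 0.0, 10_000.0, 20_000.0)  # 10 km x 20 km
        assert area_km2(rect, CEA) == pytest.approx(200.0)

    def test_mask_and_polygonized_mask_agree(self):
        """Raster and vector area paths differ by less than one pixel."""
        from shapely.ops import unary_union

        rng = np.random.default_rng(2)
        mask = rng.random((15, 15)) < 0.4
        aoh = flat_aoh(shape=(15, 15), mask=mask)
        t = aoh.transform
        boxes = [box(*t * (c, r + 1), *t * (c + 1, r))
                 for r, c in zip(*np.nonzero(mask))]
        poly = unary_union(boxes)
        assert abs(area_km2(aoh) - area_km2(poly, CEA)) < 1.0

    def test_geographic_polygon_rejected(self):
        with pytest.raises(ParameterError):
            area_km2(box(0, 0, 1, 1), WGS84)


def summary(cat="LC", ratio=1.0, flags=(), n=50):
    return SpeciesSummary(species_id=f"sp-{cat}-{ratio}",
                          redlist_category=cat,
                          published_range_km2=100.0, aoh_km2=100.0 * ratio,
                          occupied_km2=60.0 * ratio,
                          unoccupied_km2=40.0 * ratio,
                          n_presences=n, flags=set(flags))


class TestSummaries:
    def test_ratio_one_when_equal(self):
        s = summarize_species("sp", "LC", 250.0,
                              flat_aoh(mask=np.ones((50, 5), dtype=bool),
                                       shape=(50, 5)), None, 50)
        assert s.ratio_aoh_range == pytest.approx(1.0)

    def test_lt10_flag(self):
        s = summarize_species("sp", "LC", 100.0, None, None, 8)
        assert "lt10_obs" in s.flags

    def test_occupied_plus_unoccupied_equals_aoh(self):
        from aohmap.occupancy import partition_aoh, AbsenceGrid
        from test_occupancy import absence_grid_at

        rng = np.random.default_rng(1)
        mask = rng.random((30, 30)) < 0.7
        aoh = flat_aoh(shape=(30, 30), mask=mask)
        part = partition_aoh(aoh, rng.uniform(0, 30_000, (8, 2)),
                             absence_grid_at(rng.uniform(0, 30_000, (3, 2))))
        s = summarize_species("sp", "VU", 500.0, aoh, part, 30)
        assert s.occupied_km2 + s.unoccupied_km2 == pytest.approx(s.aoh_km2)


class TestCategoryTable:
    def test_single_species_extreme_ratio(self):
        tab = category_table([summary("LC", 2.0)]).table
        assert tab.loc["LC", "frac_gt_high"] == 1.0

    def test_hand_binned_cohort(self):
        tab = category_table([summary("EN", r) for r in (0.3, 0.8, 1.6)]).table
        row = tab.loc["EN"]
        assert (row["frac_lt_low"], row["frac_mid"], row["frac_gt_high"]) \
            == (pytest.approx(1 / 3), pytest.approx(1 / 3),
                pytest.approx(1 / 3))
        assert row["frac_gt_100"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        summaries = [summary(cat, float(r))
                     for cat in ("CR", "EN", "VU", "NT", "LC")
                     for r in rng.uniform(0.1, 3.0, 7)]
        tab = category_table(summaries).table
        sums = tab[["frac_lt_low", "frac_mid", "frac_gt_high"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_flagged_species_excluded(self):
        usable = [summary("VU", 0.4), summary("VU", 2.0)]
        flagged = [summary("VU", 9.9, flags=["lt10_obs"]),
                   summary("VU", 9.9, flags=["open_habitat"])]
        tab = category_table(usable + flagged).table
        assert tab.loc["VU", "n"] == 2
        assert tab.loc["VU", "frac_gt_high"] == 0.5

    def test_empty_input_errors(self):
        with pytest.raises(ParameterError):
            category_table([summary("LC", 1.0, flags=["lt10_obs"])])


@pytest.fixture(scope="module")
def batch_dir(tmp_path_factory):
    """Three-species fixture batch; one species has zero records."""
    d = tmp_path_factory.mktemp("batch")
    land = fx.make_landscape(1, (80, 80), "gradient", 0.55)
    fx.write_landscape(land, d)
    species, records = [], []
    for k in range(2):
        sp = fx.make_species(300 + k, land, elev_band=(600, 2400),
                             cover_min=40, range_fraction=0.6,
                             detect_prob=0.9)
        species.append(sp)
        records.extend(fx.simulate_checklists(400 + k, land, sp, 1500))
    ghost = fx.make_species(310, land, elev_band=(600, 2400), cover_min=40,
                            range_fraction=0.3, species_id="Ghostus nullus")
    species.append(ghost)  # metadata and range exist; no checklists detect it
    fx.write_range_geojson(species, d / "ranges.geojson")
    fx.write_checklists_tsv(records, d / "checklists.tsv")
    fx.write_meta_csv(species, d / "meta.csv")
    return d, species


def make_config(d, **over):
    kwargs = dict(checklists=d / "checklists.tsv",
                  ranges=d / "ranges.geojson", meta=d / "meta.csv",
                  elevation=d / "elevation.tif", cover=d / "cover.tif",
                  out_dir=d / "out")
    kwargs.update(over)
    return BatchConfig(**kwargs)


class TestRunBatch:
    def test_summaries_and_exclusions(self, batch_dir):
        d, species = batch_dir
        res = run_batch(make_config(d))
        assert len(res.summaries) == 2
        assert ("Ghostus nullus", "no_qualifying_records") in res.exclusions
        assert (res.out_dir / "species_summary.csv").exists()

    def test_rerun_is_byte_identical(self, batch_dir):
        d, _ = batch_dir
        run_batch(make_config(d, out_dir=d / "o1", write_maps=False))
        run_batch(make_config(d, out_dir=d / "o2", write_maps=False))
        for name in ("species_summary.csv", "exclusions.csv"):
            assert (d / "o1" / name).read_bytes() == \
                (d / "o2" / name).read_bytes()

    def test_large_range_screen(self, batch_dir):
        d, species = batch_dir
        pub = {species[0].species_id: 130_000.0}
        fx.write_meta_csv(species, d / "meta_screen.csv",
                          published_range_km2=pub)
        res = run_batch(make_config(d, meta=d / "meta_screen.csv",
                                    out_dir=d / "o3", write_maps=False))
        assert (species[0].species_id, "range_above_threshold") \
            in res.exclusions

    def test_summary_csv_round_trips(self, batch_dir):
        d, _ = batch_dir
        res = run_batch(make_config(d, out_dir=d / "o4", write_maps=False))
        df = pd.read_csv(d / "o4" / "species_summary.csv")
        by_id = {r["species_id"]: r for _, r in df.iterrows()}
        for s in res.summaries:
            row = by_id[s.species_id]
            assert row["aoh_km2"] == pytest.approx(s.aoh_km2, abs=1e-5)
            assert row["n_presences"] == s.n_presences

    def test_unreadable_config_errors(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("paths: {checklists: a.tsv}")  # missing keys
        with pytest.raises(ParameterError):
            run_batch(cfg)


class TestExportMap:
    @pytest.fixture()
    def artifacts(self, landscape, species):
        from aohmap.crs import lonlat_to_cea
        from aohmap.habitat import annotate_presences, compute_aoh, \
            ElevationLimits, HabitatThreshold
        from aohmap.hull import species_hull
        from aohmap.ingest import extract_presences, filter_checklists
        from aohmap.occupancy import build_absence_grid, partition_aoh

        records = filter_checklists(
            fx.simulate_checklists(21, landscape, species, 4000,
                                   effort_field="clustered"))
        pres = extract_presences(records, species.species_id)
        ll = pres.lonlat()
        x, y = lonlat_to_cea(ll[:, 0], ll[:, 1])
        hull = species_hull(np.column_stack([x, y]),
                            species.true_range_wgs84)
        annotate_presences(pres, landscape.elevation, landscape.cover)
        lim = ElevationLimits(species.true_elev_min, species.true_elev_max,
                              None, None, species.true_elev_min,
                              species.true_elev_max)
        thr = HabitatThreshold(species.true_cover_min, 10, 0)
        aoh = compute_aoh(hull.geometry, landscape.elevation, landscape.cover,
                          lim, thr)
        absences = build_absence_grid(records, species.species_id, aoh)
        part = partition_aoh(aoh, pres, absences) if aoh.n_pixels else None
        return dict(hull=hull, presences=pres, absences=absences,
                    partition=part, published=species.true_range_wgs84)

    def test_one_layer_per_nonempty_input(self, tmp_path, artifacts, species):
        path = export_map(tmp_path / "m.html", species.species_id,
                          hull=artifacts["hull"],
                          partition=artifacts["partition"],
                          presences=artifacts["presences"],
                          absences=artifacts["absences"],
                          published_range=artifacts["published"])
        html = path.read_text()
        for layer in ("Published range", "Alpha hull", "Area of Habitat",
                      "Presences"):
            assert layer in html
        if len(artifacts["absences"]):
            assert "Inferred absences" in html

    def test_presence_popup_contains_checklist_id(self, tmp_path, artifacts,
                                                  species):
        path = export_map(tmp_path / "m.html", species.species_id,
                          presences=artifacts["presences"])
        html = path.read_text()
        assert artifacts["presences"].points[0].checklist_id in html

    def test_absence_popup_contains_count(self, tmp_path, species):
        from test_occupancy import absence_grid_at

        absences = absence_grid_at([(12_500.0, 7_500.0)])
        absences.cells[0].n_checklists = 31
        path = export_map(tmp_path / "m.html", species.species_id,
                          absences=absences)
        assert "31 non-detection" in path.read_text()

    def test_no_absence_layer_when_empty(self, tmp_path, artifacts, species):
        from aohmap.occupancy import AbsenceGrid

        path = export_map(tmp_path / "m.html", species.species_id,
                          presences=artifacts["presences"],
                          absences=AbsenceGrid())
        assert "Inferred absences" not in path.read_text()

    def test_overlay_points_marked_display_only(self, tmp_path, artifacts,
                                                species):
        path = export_map(tmp_path / "m.html", species.species_id,
                          presences=artifacts["presences"],
                          overlay_points=[(-74.2, 4.8, "Historical record")])
        html = path.read_text()
        assert "excluded from analysis" in html

    def test_no_layers_errors(self, tmp_path, species):
        with pytest.raises(ParameterError):
            export_map(tmp_path / "m.html", species.species_id)


class TestEndToEndOccupancyDesign:
    def test_unoccupied_fraction_matches_survey_design(self):
        """A species confined to the east half of a uniform habitat block,
        surveyed densely everywhere, should come out roughly half
        Potentially Occupied (east, where it is detected) and half
        Potentially Unoccupied (west, tiled by inferred-absence cells)."""
        from shapely.geometry import MultiPolygon, box
        from aohmap.crs import Affine, CEA, lonlat_to_cea
        from aohmap.fixtures import Landscape, VirtualSpecies
        from aohmap.habitat import (annotate_presences, compute_aoh,
                                    cover_threshold, elevation_limits)
        from aohmap.hull import species_hull
        from aohmap.ingest import extract_presences, filter_checklists
        from aohmap.occupancy import build_absence_grid, partition_aoh
        from aohmap.raster import Raster

        n = 100
        t = Affine.from_origin(0.0, n * 1000.0, 1000.0, 1000.0)
        land = Landscape(elevation=Raster(np.full((n, n), 1000.0), t, CEA),
                         cover=Raster(np.full((n, n), 80.0), t, CEA),
                         pixel_km=1.0)
        east = box(50_000.0, 0.0, 100_000.0, 100_000.0)
        from aohmap.crs import geom_to_wgs84
        sp = VirtualSpecies(
            species_id="Orientalis dimidius",
            true_range=MultiPolygon([east]),
            true_range_wgs84=geom_to_wgs84(MultiPolygon([east])),
            true_elev_min=0.0, true_elev_max=2000.0, true_cover_min=0.0,
            detect_prob=1.0, redlist_category="VU")
        records = filter_checklists(fx.simulate_checklists(
            99, land, sp, 16000, effort_field="uniform",
            violation_fraction=0.1))
        pres = extract_presences(records, sp.species_id)
        ll = pres.lonlat()
        x, y = lonlat_to_cea(ll[:, 0], ll[:, 1])
        published = geom_to_wgs84(box(0.0, 0.0, 100_000.0, 100_000.0))
        hull = species_hull(np.column_stack([x, y]), published, alpha_km=1e6)
        annotate_presences(pres, land.elevation, land.cover)
        aoh = compute_aoh(hull.geometry, land.elevation, land.cover,
                          elevation_limits(pres), cover_threshold(pres))
        assert aoh.n_pixels == n * n  # uniform habitat: whole block is AOH
        absences = build_absence_grid(records, sp.species_id, aoh)
        assert len(absences) > 0
        part = partition_aoh(aoh, pres, absences)
        unoccupied_fraction = part.n_unoccupied / aoh.n_pixels
        assert abs(unoccupied_fraction - 0.5) <= 0.1
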