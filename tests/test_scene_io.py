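"""Scene model, GeoJSON/mask readers and metadata parsing."""

import json
import math

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon, box

from tlsquant import (
    ExclusionRegion,
    MarkerProfile,
    QuantConfig,
    TissueScene,
    read_cohort_metadata,
    read_scene,
    write_scene,
)
from tlsquant.io import mask_label_to_polygons, repair_polygon

from conftest import disc_scene, make_tls


class TestRoundTrip:
    def test_geojson_round_trip_preserves_areas_and_fields(self, tmp_path):
        scene = disc_scene(
            exclusions=[ExclusionRegion(Point(10, 10).buffer(0.5), "necrosis")],
            tls=[make_tls("a", 6.5, 10.0), make_tls("b", 14.0, 10.0)],
        )
        scene.pixel_size = 10.0
        scene.metadata = {"stage": "primary", "site": "skin"}
        path = tmp_path / "s.geojson"
        write_scene(scene, path)
        back = read_scene(path)

        assert back.sample_id == scene.sample_id
        assert abs(back.tissue.area - scene.tissue.area) < 1e-9
        assert abs(back.tumor_nests.area - scene.tumor_nests.area) < 1e-9
        assert [e.category for e in back.exclusions] == ["necrosis"]
        assert back.metadata == scene.metadata
        assert len(back.tls_candidates) == 2
        for orig, rt in zip(scene.tls_candidates, back.tls_candidates):
            assert rt.tls_id == orig.tls_id
            assert abs(rt.outline.area - orig.outline.area) < 1e-9
            assert rt.markers.fractions == pytest.approx(orig.markers.fractions)

    def test_empty_candidate_list_round_trips(self, tmp_path):
        scene = disc_scene()
        path = tmp_path / "s.geojson"
        write_scene(scene, path)
        back = read_scene(path)
        assert back.tls_candidates == []

    def test_gc_region_round_trips(self, tmp_path):
        tls = make_tls("a", 6.5, 10.0, radius=0.2)
        tls.gc_region = Point(6.5, 10.0).buffer(0.1)
        tls.gc_bcl6_status = "negative"
        scene = disc_scene(tls=[tls])
        path = tmp_path / "s.geojson"
        write_scene(scene, path)
        back = read_scene(path)
        assert abs(back.tls_candidates[0].gc_region.area - tls.gc_region.area) < 1e-9
        assert back.tls_candidates[0].gc_bcl6_status == "negative"


class TestReaderErrors:
    def test_missing_calibration_is_hard_error(self, tmp_path):
        path = tmp_path / "s.geojson"
        fc = {"type": "FeatureCollection", "features": []}
        path.write_text(json.dumps(fc))
        with pytest.raises(ValueError, match="calibration"):
            read_scene(path)

    def test_unknown_class_lists_offenders(self, tmp_path):
        path = tmp_path / "s.geojson"
        square = {"type": "Polygon",
                  "coordinates": [[[0, 0], [100, 0], [100, 100], [0, 100], [0, 0]]]}
        fc = {"type": "FeatureCollection", "pixel_size_um": 100.0, "features": [
            {"type": "Feature", "geometry": square,
             "properties": {"classification": {"name": "Tissue"}}},
            {"type": "Feature", "geometry": square,
             "properties": {"classification": {"name": "Mystery"}}},
        ]}
        path.write_text(json.dumps(fc))
        with pytest.raises(ValueError, match="Mystery"):
            read_scene(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_scene(tmp_path / "nope.geojson")


class TestPolygonRepair:
    def test_bowtie_decomposes_into_two_triangles(self):
        # bow-tie crossing at the origin: two triangles of area 1 each
        bowtie = Polygon([(-2, -1), (2, 1), (2, -1), (-2, 1)])
        assert not bowtie.is_valid
        repaired = repair_polygon(bowtie, label="bowtie")
        # manual decomposition: triangles ((-2,-1),(0,0),(-2,1)) and
        # ((2,-1),(0,0),(2,1)), each with base 2 and height 2 -> area 2*2/2 = 2
        assert repaired.area == pytest.approx(4.0, abs=1e-12)
        assert len(repaired.geoms) == 2

    def test_degenerate_polygon_dropped(self):
        sliver = Polygon([(0, 0), (1e-4, 0), (1e-4, 1e-4), (0, 1e-4)])
        assert repair_polygon(sliver, min_area_mm2=1e-6) is None


class TestMaskReading:
    def test_square_label_area_matches_pixel_count(self, tmp_path):
        import tifffile

        mask = np.zeros((300, 300), dtype=np.uint8)
        mask[20:280, 20:280] = 1  # tissue
        mask[100:200, 100:200] = 2  # tumor: 10,000 px
        path = tmp_path / "m.tif"
        tifffile.imwrite(path, mask)
        sidecar = {"pixel_size_um": 10.0,
                   "labels": {"1": "tissue", "2": "tumor"}}
        (tmp_path / "m.tif.json").write_text(json.dumps(sidecar))
        scene = read_scene(path)
        # 10 um/px -> 0.01 mm/px: a 10,000 px square label is 1 mm^2 up to
        # the 0.5 px^2 corner chamfer of the contour tracer
        assert scene.tumor_nests.area == pytest.approx(1.0, rel=1e-3)
        assert scene.tissue.area == pytest.approx(260 * 260 * 1e-4, rel=1e-3)

    def test_blob_label_area_within_one_percent(self):
        yy, xx = np.mgrid[0:300, 0:300]
        blob = ((xx - 150) ** 2 + (yy - 150) ** 2 <= 60 ** 2).astype(np.uint8)
        mp = mask_label_to_polygons(blob, 1, mm_per_px=0.01)
        pixel_area = blob.sum() * 1e-4
        assert mp.area == pytest.approx(pixel_area, rel=0.01)

    def test_label_with_hole(self):
        mask = np.zeros((100, 100), dtype=np.uint8)
        mask[10:90, 10:90] = 1
        mask[40:60, 40:60] = 0
        mp = mask_label_to_polygons(mask, 1, mm_per_px=1.0)
        assert mp.area == pytest.approx(80 * 80 - 20 * 20, rel=1e-9)


class TestCohortMetadata:
    def test_parse_typical_rows(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "sample_id,stage,site,breslow_mm,ulceration,age,sex\n"
            "S1,primary,skin,2.73,present,67,male\n"
            "S2,late_met,lymph_node,,,55,female\n"
        )
        meta = read_cohort_metadata(path)
        assert meta["S1"]["stage"] == "primary"
        assert meta["S1"]["breslow_mm"] == pytest.approx(2.73)
        assert "breslow_mm" not in meta["S2"]  # optional Breslow may be absent
        assert meta["S2"]["site"] == "lymph_node"

    def test_duplicate_sample_id_is_error(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("sample_id,stage\nS1,primary\nS1,late_met\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort_metadata(path)

    def test_unknown_vocabulary_warns_but_passes(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("sample_id,stage,site\nS1,weird_stage,skin\n")
        with pytest.warns(UserWarning, match="weird_stage"):
            meta = read_cohort_metadata(path)
        assert meta["S1"]["stage"] == "weird_stage"


class TestSceneInvariants:
    def test_marker_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MarkerProfile({"CD4": 1.5})

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError):
            MarkerProfile({"CD8": 0.5})

    def test_exclusion_category_vocabulary(self):
        with pytest.raises(ValueError):
            ExclusionRegion(box(0, 0, 1, 1), "artifact")

    def test_tumor_outside_tissue_rejected(self):
        scene = TissueScene(
            sample_id="bad",
            tissue=MultiPolygon([box(0, 0, 10, 10)]),
            tumor_nests=MultiPolygon([box(8, 8, 14, 14)]),
        )
        with pytest.raises(ValueError, match="outside tissue"):
            scene.validate()
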