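"""Invasive front, distance bands, assignment and partition invariants."""

import math

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, box
import shapely.affinity as aff

from tlsquant import (
    BEYOND,
    DROPPED,
    ExclusionRegion,
    QuantConfig,
    TissueScene,
    assign_tls_to_band,
    build_bands,
    derive_invasive_front,
    derive_tumor_region,
)

from conftest import disc_scene, make_tls


def nests_scene(nests, extent=(20.0, 20.0)) -> TissueScene:
    return TissueScene(
        sample_id="nests",
        tissue=MultiPolygon([box(0, 0, *extent)]),
        tumor_nests=MultiPolygon(nests),
    )


class TestTumorRegion:
    def test_single_convex_nest_unchanged(self):
        scene = disc_scene(tumor_radius=3.0)
        region = derive_tumor_region(scene, closing_radius_mm=0.5)
        assert region.area == pytest.approx(scene.tumor_nests.area, rel=1e-6)

    def test_close_nests_merge_across_septum(self):
        # two 1 mm discs, gap 0.4 mm < 2 * closing radius
        nests = [Point(8.0, 10.0).buffer(1.0, quad_segs=64),
                 Point(10.4, 10.0).buffer(1.0, quad_segs=64)]
        region = derive_tumor_region(nests_scene(nests), closing_radius_mm=0.5)
        assert len(region.geoms) == 1
        # merged region covers both nests plus the septum between them
        assert region.area > sum(n.area for n in nests)

    def test_distant_nests_stay_apart(self):
        nests = [Point(6.0, 10.0).buffer(1.0, quad_segs=64),
                 Point(10.0, 10.0).buffer(1.0, quad_segs=64)]  # gap 2 mm
        region = derive_tumor_region(nests_scene(nests), closing_radius_mm=0.5)
        assert len(region.geoms) == 2

    def test_no_tumor_is_error(self):
        scene = TissueScene("x", MultiPolygon([box(0, 0, 5, 5)]), MultiPolygon([]))
        with pytest.raises(ValueError, match="no tumor"):
            derive_tumor_region(scene)


class TestInvasiveFront:
    def test_centered_disc_front_is_full_circle(self):
        scene = disc_scene(tumor_radius=3.0)
        region = derive_tumor_region(scene, 0.0)
        front = derive_invasive_front(region, scene.tissue)
        assert front.length == pytest.approx(2 * math.pi * 3.0, rel=1e-3)

    def test_edge_touching_square_keeps_three_sides(self):
        # 4 mm square with its left side on the tissue edge
        scene = TissueScene(
            "sq",
            tissue=MultiPolygon([box(0, 0, 20, 20)]),
            tumor_nests=MultiPolygon([box(0, 8, 4, 12)]),
        )
        region = derive_tumor_region(scene, 0.0)
        front = derive_invasive_front(region, scene.tissue, edge_tolerance_mm=0.05)
        assert front.length == pytest.approx(3 * 4.0, abs=0.25)

    def test_tumor_filling_tissue_is_error(self):
        scene = TissueScene(
            "full",
            tissue=MultiPolygon([box(0, 0, 10, 10)]),
            tumor_nests=MultiPolygon([box(0, 0, 10, 10)]),
        )
        region = derive_tumor_region(scene, 0.0)
        with pytest.raises(ValueError, match="zero length"):
            derive_invasive_front(region, scene.tissue)


class TestBandAreas:
    def test_disc_annuli_match_closed_form(self):
        """Extratumoral band k of a centered disc tumor is the annulus
        pi*((r+k)^2 - (r+k-1)^2) until the tissue edge truncates it."""
        r = 3.0
        scene = disc_scene(tumor_radius=r, extent=(20.0, 20.0))
        table = build_bands(scene, config=QuantConfig(closing_radius_mm=0.0))
        extra = {(b.inner_mm, b.outer_mm): b for b in table.bands if b.compartment == "EXTRA"}
        # bands up to (5,6]: outer radius 9 < 10 mm half-extent, no truncation
        for k in range(1, 7):
            expected = math.pi * ((r + k) ** 2 - (r + k - 1) ** 2)
            assert extra[(k - 1.0, float(k))].analyzable_area == pytest.approx(
                expected, rel=1e-3)
        intra = {(b.inner_mm, b.outer_mm): b for b in table.bands if b.compartment == "INTRA"}
        assert intra[(0.0, 1.0)].analyzable_area == pytest.approx(
            math.pi * (r**2 - (r - 1) ** 2), rel=1e-3)
        assert intra[(1.0, math.inf)].analyzable_area == pytest.approx(
            math.pi * (r - 1) ** 2, rel=1e-3)

    def test_exclusion_subtracted_from_band(self):
        r = 3.0
        # 2 mm^2 necrotic disc inside the intratumoral (0,1] rim
        necro = Point(10.0 + r - 0.5, 10.0).buffer(math.sqrt(2.0 / math.pi), quad_segs=128)
        plain = build_bands(disc_scene(tumor_radius=r),
                            config=QuantConfig(closing_radius_mm=0.0))
        scene = disc_scene(tumor_radius=r,
                           exclusions=[ExclusionRegion(necro, "necrosis")])
        table = build_bands(scene, config=QuantConfig(closing_radius_mm=0.0))
        get = lambda t: t.band_for_key(("INTRA", 0.0, 1.0)).analyzable_area
        # the rim loses exactly its own overlap with the necrotic region
        lost = necro.intersection(
            plain.band_for_key(("INTRA", 0.0, 1.0)).geometry).area
        assert lost > 0
        assert get(plain) - get(table) == pytest.approx(lost, rel=1e-6)

    def test_partition_sums_to_analyzable_tissue(self):
        scene = disc_scene(
            tumor_radius=3.0,
            exclusions=[ExclusionRegion(Point(10, 10).buffer(0.8), "necrosis")],
        )
        table = build_bands(scene, config=QuantConfig(closing_radius_mm=0.0))
        expected = scene.tissue.area - scene.exclusion_union.area
        assert table.total_analyzable_area == pytest.approx(expected, abs=1e-6)
        # bands pairwise disjoint
        for i, a in enumerate(table.bands):
            for b in table.bands[i + 1:]:
                assert a.geometry.intersection(b.geometry).area < 1e-9

    def test_scale_equivariance(self):
        """Scaling coordinates and radii by c scales every band area by c^2."""
        c = 2.0
        base = disc_scene(tumor_radius=2.0, extent=(16.0, 16.0))
        scaled = TissueScene(
            "scaled",
            tissue=MultiPolygon([aff.scale(g, c, c, origin=(0, 0)) for g in base.tissue.geoms]),
            tumor_nests=MultiPolygon(
                [aff.scale(g, c, c, origin=(0, 0)) for g in base.tumor_nests.geoms]),
        )
        t1 = build_bands(base, radii=[1, 2, 3], config=QuantConfig(closing_radius_mm=0.0))
        t2 = build_bands(scaled, radii=[c, 2 * c, 3 * c],
                         config=QuantConfig(closing_radius_mm=0.0))
        for b1, b2 in zip(t1.bands, t2.bands):
            assert b2.analyzable_area == pytest.approx(c**2 * b1.analyzable_area, rel=1e-6)


@pytest.fixture(scope="module")
def banded():
    scene = disc_scene(tumor_radius=3.0)
    return scene, build_bands(scene, config=QuantConfig(closing_radius_mm=0.0))


class TestAssignment:

    def test_fully_inside_band(self, banded):
        scene, table = banded
        tls = make_tls("a", 10.0 + 3.5, 10.0, radius=0.1)  # center of EXTRA (0,1]
        assert assign_tls_to_band(tls, table) == ("EXTRA", 0.0, 1.0)

    def test_larger_share_wins(self, banded):
        scene, table = banded
        # center at distance 1.06 mm outside the front: > half of a 0.2 mm
        # disc lies in EXTRA (1,2]
        tls = make_tls("b", 10.0 + 4.06, 10.0, radius=0.2)
        assert assign_tls_to_band(tls, table) == ("EXTRA", 1.0, 2.0)

    def test_straddling_front_follows_centroid(self, banded):
        scene, table = banded
        # disc centered slightly inside the front: centroid intratumoral
        tls = make_tls("c", 10.0 + 3.0 - 0.02, 10.0, radius=0.2)
        assert assign_tls_to_band(tls, table) == ("INTRA", 0.0, 1.0)

    def test_beyond_outermost_band(self, banded):
        scene, table = banded
        tls = make_tls("d", 0.5, 0.5, radius=0.1)  # corner, ~10 mm from front
        assert assign_tls_to_band(tls, table) == BEYOND

    def test_mostly_excluded_tls_dropped(self):
        necro = Point(12.0, 10.0).buffer(1.0)
        scene = disc_scene(tumor_radius=3.0,
                           exclusions=[ExclusionRegion(necro, "necrosis")])
        table = build_bands(scene, config=QuantConfig(closing_radius_mm=0.0))
        tls = make_tls("e", 12.0, 10.0, radius=0.2)  # fully inside necrosis
        key = assign_tls_to_band(tls, table, scene.exclusion_union)
        assert key == DROPPED

    def test_every_retained_tls_assigned_once(self, banded):
        scene, table = banded
        rng = np.random.default_rng(5)
        n = 40
        keys = []
        for i in range(n):
            x, y = rng.uniform(2, 18, 2)
            keys.append(assign_tls_to_band(make_tls(f"t{i}", x, y, 0.1), table))
        band_keys = {b.key for b in table.bands}
        assert all(k in band_keys or k == BEYOND for k in keys)
        assigned = [k for k in keys if k in band_keys]
        assert len(assigned) + sum(k == BEYOND for k in keys) == n
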