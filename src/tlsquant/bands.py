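"""Invasive tumor front and intra-/extratumoral distance bands.

The tumor compartment is the morphological closing of the union of tumor
nests (default radius 0.5 mm, holes filled), so stromal septa between nearby
nests count as intratumoral stroma. Distance is Euclidean distance to the
invasive front, realized by iterated buffering of the tumor compartment.
Bands are half-open intervals (inner, outer] mm: extratumoral (0,1] ... (5,6]
by default, intratumoral (0,1] and (1, inf). Exclusion regions are subtracted
from every band's analyzable area, and bands truncated by the available
tissue keep their reduced area (normalization absorbs the truncation).
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .config import QuantConfig
from .scene import Band, BandTable, TissueScene, TLSObject, as_multipolygon

log = logging.getLogger(__name__)

#: Key of the catch-all bucket for TLS beyond the outermost extratumoral band.
BEYOND = ("BEYOND", 0.0, math.inf)
#: Marker for TLS dropped because they sit mostly inside an exclusion region.
DROPPED = ("DROPPED", 0.0, math.inf)


def _fill_holes(geom) -> MultiPolygon:
    return MultiPolygon([Polygon(p.exterior.coords) for p in as_multipolygon(geom).geoms])


def derive_tumor_region(scene: TissueScene, closing_radius_mm: float = 0.5) -> MultiPolygon:
    """Union of tumor nests, morphologically closed and clipped to tissue.

    Closing (dilate then erode by ``closing_radius_mm``) merges nests
    separated by narrow stromal septa into one tumor compartment; interior
    holes are filled.
    """
    if scene.tumor_nests.is_empty:
        raise ValueError(f"{scene.sample_id}: no tumor nests annotated")
    nests = unary_union(scene.tumor_nests)
    if closing_radius_mm > 0:
        closed = nests.buffer(closing_radius_mm).buffer(-closing_radius_mm)
        closed = closed.union(nests)  # closing never removes original area
    else:
        closed = nests
    closed = _fill_holes(closed)
    return as_multipolygon(closed.intersection(scene.tissue))


def derive_invasive_front(tumor_region, tissue, edge_tolerance_mm: float = 0.05):
    """Boundary of the tumor compartment, minus the section cut edge.

    Portions of the tumor boundary within ``edge_tolerance_mm`` of the tissue
    boundary are where the section was cut, not a biological invasive front,
    and are removed. Raises if nothing remains (tumor fills the tissue):
    such samples cannot be banded and must be excluded.
    """
    front = tumor_region.boundary.difference(tissue.boundary.buffer(edge_tolerance_mm))
    if front.is_empty or front.length <= 0:
        raise ValueError(
            "invasive front has zero length (tumor fills the tissue section); "
            "exclude this sample from spatial analysis"
        )
    return front


def build_bands(
    scene: TissueScene,
    tumor_region: Optional[MultiPolygon] = None,
    radii: Optional[Sequence[float]] = None,
    config: Optional[QuantConfig] = None,
) -> BandTable:
    """Partition the analyzable tissue into distance bands around the front.

    Extratumoral band k covers points outside the tumor compartment, inside
    tissue, with Euclidean distance to the front in (r_{k-1}, r_k];
    intratumoral bands are (0,1] and (1, inf) inside the tumor compartment.
    Every band's ``analyzable_area`` has exclusion-region overlaps removed.
    """
    config = config or QuantConfig()
    radii = list(radii if radii is not None else config.radii)
    if any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
        raise ValueError("radii must be positive, strictly increasing")
    if tumor_region is None:
        tumor_region = derive_tumor_region(scene, config.closing_radius_mm)
    front = derive_invasive_front(tumor_region, scene.tissue, config.edge_tolerance_mm)

    excl = scene.exclusion_union
    tissue = scene.tissue
    bands: list[Band] = []

    # intratumoral: (1, inf) = erosion by the first radius; (0, r1] = rest
    r1 = radii[0]
    core = as_multipolygon(tumor_region.buffer(-r1))
    rim = as_multipolygon(tumor_region.difference(core))
    for compartment, inner, outer, geom in (
        ("INTRA", r1, math.inf, core),
        ("INTRA", 0.0, r1, rim),
    ):
        g = as_multipolygon(geom.difference(excl))
        bands.append(Band(compartment, inner, outer, g, g.area))

    # extratumoral annuli clipped to tissue
    prev_buf = tumor_region
    prev_r = 0.0
    for r in radii:
        buf = tumor_region.buffer(r)
        ring = as_multipolygon(buf.difference(prev_buf).intersection(tissue).difference(excl))
        bands.append(Band("EXTRA", prev_r, r, ring, ring.area))
        prev_buf, prev_r = buf, r

    beyond = tissue.difference(prev_buf).difference(excl)
    table = BandTable(
        sample_id=scene.sample_id,
        bands=bands,
        beyond_area=float(beyond.area),
        front_length=float(front.length),
    )
    _check_partition(scene, tumor_region, table)
    return table


def _check_partition(scene: TissueScene, tumor_region, table: BandTable, tol: float = 1e-6) -> None:
    expected = scene.tissue.difference(scene.exclusion_union).area
    got = table.total_analyzable_area
    if abs(got - expected) > max(tol, 1e-6 * expected):
        log.warning(
            "%s: band partition misses tissue area by %.3g mm^2 "
            "(numerical buffering artifact)",
            scene.sample_id,
            got - expected,
        )


def assign_tls_to_band(
    tls: TLSObject,
    bands: BandTable,
    exclusion_union=None,
    exclusion_drop_fraction: float = 0.5,
) -> tuple:
    """Assign one TLS to the single band holding the larger share of its area.

    Ties are broken toward the band containing the centroid, then toward the
    more intratumoral band. TLS with at least ``exclusion_drop_fraction`` of
    their area inside exclusion regions are dropped (key ``DROPPED``); TLS
    beyond the outermost extratumoral band land in the ``BEYOND`` bucket.
    The chosen key is also written to ``tls.band_key``.
    """
    if exclusion_union is not None and not exclusion_union.is_empty:
        excl_share = tls.outline.intersection(exclusion_union).area / tls.outline.area
        if excl_share >= exclusion_drop_fraction:
            log.info(
                "TLS %s dropped: %.0f%% of area inside exclusion regions",
                tls.tls_id,
                100 * excl_share,
            )
            tls.band_key = DROPPED
            return DROPPED

    shares = [(b, tls.outline.intersection(b.geometry).area) for b in bands.bands]
    best = max(s for _, s in shares)
    if best <= 0:
        log.info("TLS %s beyond the outermost band; excluded from band statistics", tls.tls_id)
        tls.band_key = BEYOND
        return BEYOND
    tied = [b for b, s in shares if abs(s - best) <= 1e-9 * max(best, 1.0)]
    if len(tied) > 1:
        centroid = tls.outline.centroid
        with_centroid = [b for b in tied if b.geometry.contains(centroid)]
        if with_centroid:
            tied = with_centroid
        tied.sort(key=lambda b: b.sort_key())
    tls.band_key = tied[0].key
    return tls.band_key
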