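"""TLS detection from cell centroids and marker-rule phenotype classification.

Classification mirrors the marker conjunctions that define the TLS
maturation hierarchy: an early TLS is a dense CD20+ B-cell aggregate with
CXCL13+ cells and no follicular dendritic cell (FDC) network; a primary
follicular TLS adds interspersed CD4+ T cells and a CD21+ immature FDC
network (CD23-, BCL6-); a secondary follicular TLS additionally carries a
CD23+ mature FDC network, with BCL6+/- status of its germinal center.
Profiles matching none of these conjunctions (e.g. an FDC network without
CD4+ T cells, or BCL6 without a mature network) stay UNCLASSIFIED: the
hierarchy defines only the listed combinations.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union

from .config import ClassifierConfig
from .scene import (
    MARKERS,
    SECONDARY_PHENOTYPES,
    MarkerProfile,
    PhenotypeLabel,
    TLSObject,
    as_multipolygon,
)

log = logging.getLogger(__name__)


def classify_booleans(
    cd20: bool, cxcl13: bool, cd4: bool, cd21: bool, cd23: bool, bcl6: bool
) -> PhenotypeLabel:
    """Decision table over the six marker booleans (evaluated in order).

    CD4 is optional for the early phenotype (aggregates with or without
    interspersed CD4+ T cells), mandatory for the follicular ones.
    """
    if not cd20:
        return PhenotypeLabel.UNCLASSIFIED
    if cd23 and cd21 and cd4:
        return (
            PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS
            if bcl6
            else PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG
        )
    if cd21 and cd4 and not cd23 and not bcl6:
        return PhenotypeLabel.PRIMARY_FOLLICULAR
    if cxcl13 and not cd21 and not cd23 and not bcl6:
        return PhenotypeLabel.EARLY
    return PhenotypeLabel.UNCLASSIFIED


def classify(tls: TLSObject, config: Optional[ClassifierConfig] = None) -> PhenotypeLabel:
    """Classify one TLS candidate from its marker profile.

    Objects below ``min_aggregate_area`` are too small to call a lymphoid
    structure and stay UNCLASSIFIED. The label is also written back to
    ``tls.phenotype``.
    """
    config = config or ClassifierConfig()
    if tls.outline.area < config.min_aggregate_area:
        label = PhenotypeLabel.UNCLASSIFIED
    else:
        b = tls.markers.booleans(config.thresholds)
        label = classify_booleans(
            b["CD20_aggregate"], b["CXCL13"], b["CD4"],
            b["CD21_network"], b["CD23_network"], b["BCL6"],
        )
    tls.phenotype = label
    return label


def assign_gc_status(tls: TLSObject, config: Optional[ClassifierConfig] = None) -> TLSObject:
    """Fill the germinal-center subregion and BCL6 status of a secondary TLS.

    When no explicit GC polygon was annotated, the GC defaults to a concentric
    copy of the outline scaled to ``gc_default_fraction`` of its area. Called
    on a non-secondary phenotype this is a warning no-op.
    """
    config = config or ClassifierConfig()
    if tls.phenotype not in SECONDARY_PHENOTYPES:
        log.warning(
            "assign_gc_status called on %s (%s): no germinal center, skipping",
            tls.tls_id,
            tls.phenotype,
        )
        return tls
    if tls.gc_region is None or tls.gc_region.is_empty:
        import shapely.affinity as aff

        f = config.gc_default_fraction ** 0.5
        c = tls.outline.centroid
        tls.gc_region = as_multipolygon(
            aff.scale(tls.outline, xfact=f, yfact=f, origin=(c.x, c.y))
        )
    tls.gc_bcl6_status = (
        "positive"
        if tls.phenotype is PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS
        else "negative"
    )
    return tls


def classify_scene(tls_list: list[TLSObject], config: Optional[ClassifierConfig] = None) -> list[TLSObject]:
    """Classify every candidate and fill GC status of secondary follicular TLS."""
    config = config or ClassifierConfig()
    for tls in tls_list:
        classify(tls, config)
        if tls.phenotype in SECONDARY_PHENOTYPES:
            assign_gc_status(tls, config)
    return tls_list


def classification_audit(tls_list: list[TLSObject], config: Optional[ClassifierConfig] = None) -> pd.DataFrame:
    """Tidy audit table: one row per TLS with fractions, booleans and label."""
    config = config or ClassifierConfig()
    rows = []
    for tls in tls_list:
        row = {"tls_id": tls.tls_id, "area_mm2": tls.outline.area}
        for m in MARKERS:
            row[f"frac_{m}"] = tls.markers.fraction(m)
            row[f"pos_{m}"] = tls.markers.positive(m, config.thresholds)
        row["phenotype"] = (tls.phenotype or classify(tls, config)).value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection from cell centroid tables


def detect_candidate_aggregates(
    cells: pd.DataFrame, config: Optional[ClassifierConfig] = None
) -> list[TLSObject]:
    """Detect candidate B-cell aggregates from a wide-format cell table.

    CD20+ cells are clustered by fixed-radius single linkage
    (``link_radius_um``); clusters with at least ``min_cd20_cells`` members
    become candidates. The outline is the union of ``cell_disc_radius_um``
    discs around member cells; marker fractions are the fraction of all cells
    inside the outline positive for each marker. CXCL13 is measured inside
    the outline plus a ``cxcl13_collar_um`` collar, since the chemokine is
    often expressed by cells surrounding, not inside, young aggregates.
    """
    config = config or ClassifierConfig()
    cd20_col = next((c for c in cells.columns if c.lower() in ("cd20", "cd20_aggregate")), None)
    if cd20_col is None:
        raise ValueError("cell table has no CD20 positivity column")

    mm = 1.0 / 1000.0
    cd20 = cells[cells[cd20_col]]
    if cd20.empty:
        return []
    xy = cd20[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(config.link_radius_um, output_type="ndarray")
    n = len(xy)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    ) if len(pairs) else coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)

    marker_cols = _marker_columns(cells)
    all_xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    candidates: list[TLSObject] = []
    for k, lab in enumerate(np.unique(labels)):
        member = xy[labels == lab]
        if len(member) < config.min_cd20_cells:
            continue
        outline = unary_union(
            [Point(x * mm, y * mm).buffer(config.cell_disc_radius_um * mm, quad_segs=8)
             for x, y in member]
        )
        outline = as_multipolygon(outline)
        inside = _points_in(all_xy * mm, outline)
        collar = outline.buffer(config.cxcl13_collar_um * mm)
        in_collar = _points_in(all_xy * mm, collar)
        fractions: dict[str, float] = {}
        n_in = int(inside.sum())
        for marker, col in marker_cols.items():
            pos = cells[col].to_numpy(dtype=bool)
            if marker == "CXCL13":
                denom = int(in_collar.sum())
                fractions[marker] = float((pos & in_collar).sum() / denom) if denom else 0.0
            else:
                fractions[marker] = float((pos & inside).sum() / n_in) if n_in else 0.0
        candidates.append(
            TLSObject(tls_id=f"agg_{len(candidates)}", outline=outline, markers=MarkerProfile(fractions))
        )
    return candidates


def _marker_columns(cells: pd.DataFrame) -> dict[str, str]:
    aliases = {
        "CD20_aggregate": ("cd20", "cd20_aggregate"),
        "CXCL13": ("cxcl13",),
        "CD4": ("cd4",),
        "CD21_network": ("cd21", "cd21_network"),
        "CD23_network": ("cd23", "cd23_network"),
        "BCL6": ("bcl6",),
    }
    out = {}
    lower = {c.lower(): c for c in cells.columns}
    for marker, names in aliases.items():
        for name in names:
            if name in lower:
                out[marker] = lower[name]
                break
    return out


def _points_in(xy_mm: np.ndarray, geom) -> np.ndarray:
    from shapely import contains_xy

    return contains_xy(geom, xy_mm[:, 0], xy_mm[:, 1])
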