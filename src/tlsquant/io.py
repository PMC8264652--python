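"""Readers and writers for the formats the pipeline touches.

Scenes travel as QuPath-style GeoJSON FeatureCollections (one file per
sample, features carrying a ``classification.name`` property) or as integer
label masks (TIFF/PNG) with a JSON sidecar giving the label->category map and
the micron calibration. Cell centroid tables and cohort metadata are plain
CSV. GeoJSON coordinates are interpreted as pixel units; a ``pixel_size_um``
calibration (file property, sidecar, or config fallback) is mandatory, and
all geometry is converted to millimeters on read.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from skimage import measure

from .config import QuantConfig
from .scene import (
    EXCLUSION_CATEGORIES,
    MARKERS,
    SITES,
    STAGES,
    ExclusionRegion,
    MarkerProfile,
    PhenotypeLabel,
    TissueScene,
    TLSObject,
    as_multipolygon,
    union_polygons,
)

log = logging.getLogger(__name__)

MASK_SUFFIXES = {".tif", ".tiff", ".png"}


# ---------------------------------------------------------------------------
# polygon repair


def repair_polygon(geom, min_area_mm2: float = 1e-6, label: str = "") -> Optional[MultiPolygon]:
    """Repair an invalid polygon, keeping every areal part.

    Self-intersecting outlines (e.g. hand-drawn "bow-ties") are decomposed
    into their valid areal parts via ``make_valid`` (zero-width buffering can
    silently discard whole lobes). Polygons whose post-repair area falls
    below ``min_area_mm2`` are dropped (degenerate annotation) with a warning.
    """
    if not geom.is_valid:
        from shapely.validation import make_valid

        log.warning("repairing invalid polygon %s", label)
        geom = make_valid(geom)
    mp = as_multipolygon(geom)
    if mp.area < min_area_mm2:
        log.warning("dropping degenerate polygon %s (area %.3g mm^2)", label, mp.area)
        return None
    return mp


# ---------------------------------------------------------------------------
# GeoJSON scenes


def _classification_name(props: dict) -> Optional[str]:
    cls = props.get("classification")
    if isinstance(cls, dict):
        return cls.get("name")
    if isinstance(cls, str):
        return cls
    return None


def _scale_geom(geom, factor: float):
    import shapely.affinity as aff

    return aff.scale(geom, xfact=factor, yfact=factor, origin=(0, 0))


def read_scene(
    annotation_path: str | Path,
    cells_path: Optional[str | Path] = None,
    config: Optional[QuantConfig] = None,
) -> TissueScene:
    """Read one annotated sample into a calibrated :class:`TissueScene`.

    ``annotation_path`` may be GeoJSON (.geojson/.json) or an integer label
    mask (.tif/.tiff/.png with a JSON sidecar). When ``cells_path`` is given
    and the annotations carry no TLS objects, candidate aggregates are
    detected from the CD20+ cell centroids.
    """
    config = config or QuantConfig()
    path = Path(annotation_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in MASK_SUFFIXES:
        scene = _read_scene_mask(path, config)
    else:
        scene = _read_scene_geojson(path, config)
    scene.tumor_nests = as_multipolygon(scene.tumor_nests.intersection(scene.tissue))
    if scene.tissue.is_empty or scene.tissue.area <= 0:
        raise ValueError(f"{path}: empty tissue region")
    if cells_path is not None and not scene.tls_candidates:
        from .phenotype import detect_candidate_aggregates

        cells = read_cells(cells_path)
        scene.tls_candidates = detect_candidate_aggregates(cells, config.classifier)
    scene.validate()
    return scene


def _map_category(name: str, class_map: dict[str, str]) -> Optional[str]:
    lower = {k.lower(): v for k, v in class_map.items()}
    return lower.get(name.lower())


def _read_scene_geojson(path: Path, config: QuantConfig) -> TissueScene:
    with open(path) as fh:
        fc = json.load(fh)
    pixel_size = fc.get("pixel_size_um", config.pixel_size_um)
    if pixel_size is None or not pixel_size > 0:
        raise ValueError(
            f"{path}: no micron calibration (pixel_size_um) in file or config"
        )
    mm_per_px = pixel_size / 1000.0

    tissue_parts: list = []
    tumor_parts: list = []
    exclusions: list[ExclusionRegion] = []
    tls_list: list[TLSObject] = []
    gc_features: list[tuple[str, MultiPolygon]] = []
    unknown: set[str] = set()

    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {}) or {}
        name = _classification_name(props)
        if name is None:
            unknown.add("<missing classification>")
            continue
        category = _map_category(name, config.class_map)
        if category is None and name.lower() == "gc":
            category = "gc"
        if category is None:
            unknown.add(name)
            continue
        geom = shape(feat["geometry"])
        geom = _scale_geom(geom, mm_per_px)
        repaired = repair_polygon(geom, config.min_polygon_area_mm2, f"{path.name}#{i}")
        if repaired is None:
            continue
        if category == "tissue":
            tissue_parts.append(repaired)
        elif category == "tumor":
            tumor_parts.append(repaired)
        elif category in EXCLUSION_CATEGORIES:
            exclusions.append(ExclusionRegion(repaired, category))
        elif category == "gc":
            gc_features.append((props.get("tls_id", ""), repaired))
        elif category == "tls":
            fracs = {
                m: float(v)
                for m, v in (props.get("measurements") or {}).items()
                if m in MARKERS
            }
            phen = props.get("phenotype")
            tls_list.append(
                TLSObject(
                    tls_id=str(props.get("tls_id", f"tls_{len(tls_list)}")),
                    outline=repaired,
                    markers=MarkerProfile(fracs),
                    gc_bcl6_status=props.get("gc_bcl6_status"),
                    phenotype=PhenotypeLabel(phen) if phen else None,
                )
            )
    if unknown:
        raise ValueError(
            f"{path}: annotation classes with no mapping: {sorted(unknown)}"
        )
    # attach GC subregions to their parent TLS
    by_id = {t.tls_id: t for t in tls_list}
    for tls_id, gc in gc_features:
        parent = by_id.get(tls_id)
        if parent is None:
            log.warning("%s: GC region for unknown TLS %r ignored", path.name, tls_id)
            continue
        parent.gc_region = as_multipolygon(gc.intersection(parent.outline))

    return TissueScene(
        sample_id=str(fc.get("sample_id", path.stem)),
        tissue=union_polygons(tissue_parts) if tissue_parts else MultiPolygon([]),
        tumor_nests=union_polygons(tumor_parts) if tumor_parts else MultiPolygon([]),
        exclusions=exclusions,
        tls_candidates=tls_list,
        metadata=dict(fc.get("metadata", {})),
        pixel_size=float(pixel_size),
    )


def write_scene(scene: TissueScene, path: str | Path) -> None:
    """Write a scene as a GeoJSON FeatureCollection (pixel coordinates)."""
    pixel_size = scene.pixel_size or 1000.0  # 1 px = 1 mm when uncalibrated
    px_per_mm = 1000.0 / pixel_size

    def feat(geom, name: str, extra: Optional[dict] = None) -> dict:
        props = {"classification": {"name": name}}
        props.update(extra or {})
        return {
            "type": "Feature",
            "geometry": mapping(_scale_geom(geom, px_per_mm)),
            "properties": props,
        }

    features = []
    for g in scene.tissue.geoms:
        features.append(feat(g, "Tissue"))
    for g in scene.tumor_nests.geoms:
        features.append(feat(g, "Tumor"))
    cat_names = {v: k for k, v in QuantConfig().class_map.items()}
    for ex in scene.exclusions:
        features.append(feat(ex.polygon, cat_names.get(ex.category, ex.category)))
    for tls in scene.tls_candidates:
        extra = {
            "tls_id": tls.tls_id,
            "measurements": {m: tls.markers.fraction(m) for m in MARKERS},
        }
        if tls.phenotype is not None:
            extra["phenotype"] = tls.phenotype.value
        if tls.gc_bcl6_status is not None:
            extra["gc_bcl6_status"] = tls.gc_bcl6_status
        features.append(feat(tls.outline, "TLS", extra))
        if tls.gc_region is not None and not tls.gc_region.is_empty:
            features.append(feat(tls.gc_region, "GC", {"tls_id": tls.tls_id}))

    fc = {
        "type": "FeatureCollection",
        "sample_id": scene.sample_id,
        "pixel_size_um": pixel_size,
        "metadata": scene.metadata,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


# ---------------------------------------------------------------------------
# label masks


def mask_label_to_polygons(mask: np.ndarray, label: int, mm_per_px: float) -> MultiPolygon:
    """Vectorize one label of an integer mask into a MultiPolygon (mm).

    Contours are traced at the 0.5 iso-level of the padded binary mask
    (marching squares chamfers each convex corner by 1/8 px^2, keeping areas
    well within 1% of the pixel count for blobs of >= 100 px); rings are
    classified as shells or holes by even-odd containment.
    """
    binary = np.pad((mask == label).astype(np.uint8), 1)
    contours = measure.find_contours(binary, 0.5)
    rings = []
    for c in contours:
        # find_contours yields (row, col); convert to (x, y) and undo padding
        xy = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0]) * mm_per_px
        if len(xy) >= 4:
            p = Polygon(xy)
            if p.is_valid and p.area > 0:
                rings.append(p)
    if not rings:
        return MultiPolygon([])
    rings.sort(key=lambda p: p.area, reverse=True)
    shells: list[Polygon] = []
    holes_by_shell: dict[int, list] = {}
    for p in rings:
        depth = sum(1 for q in shells if q.contains(p.representative_point()))
        if depth % 2 == 0:
            shells.append(p)
            holes_by_shell[len(shells) - 1] = []
        else:
            # hole in the innermost containing shell
            for j in range(len(shells) - 1, -1, -1):
                if shells[j].contains(p.representative_point()):
                    holes_by_shell[j].append(p.exterior.coords)
                    break
    return MultiPolygon(
        [Polygon(s.exterior.coords, holes_by_shell[j]) for j, s in enumerate(shells)]
    )


def _read_scene_mask(path: Path, config: QuantConfig) -> TissueScene:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    pixel_size = meta.get("pixel_size_um", config.pixel_size_um)
    if pixel_size is None or not pixel_size > 0:
        raise ValueError(f"{path}: no micron calibration for mask")
    mm_per_px = pixel_size / 1000.0

    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        mask = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        mask = iio.imread(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{path}: label mask must be 2-D, got shape {mask.shape}")

    label_map = {int(k): v for k, v in meta.get("labels", {}).items()}
    present = set(np.unique(mask)) - {0}
    unknown = sorted(present - set(label_map))
    if unknown:
        raise ValueError(f"{path}: mask labels with no mapping: {unknown}")

    tumor_parts, exclusions, tls_list = [], [], []
    for label in sorted(present):
        category = label_map[label]
        if category == "tissue":
            continue  # tissue is traced from the composite foreground below
        mp = mask_label_to_polygons(mask, label, mm_per_px)
        if mp.is_empty:
            continue
        if category == "tumor":
            tumor_parts.append(mp)
        elif category in EXCLUSION_CATEGORIES:
            exclusions.append(ExclusionRegion(mp, category))
        elif category == "tls":
            for j, g in enumerate(mp.geoms):
                tls_list.append(TLSObject(tls_id=f"tls_{label}_{j}", outline=g))
        else:
            raise ValueError(f"{path}: unknown mask category {category!r}")

    # label masks partition the section: every labeled pixel is tissue, so
    # trace the composite foreground in one pass (avoids hairline seams
    # between adjacent label contours)
    binary = (mask != 0).astype(np.uint8)
    tissue_parts = [mask_label_to_polygons(binary, 1, mm_per_px)]

    return TissueScene(
        sample_id=str(meta.get("sample_id", path.stem)),
        tissue=union_polygons(tissue_parts) if tissue_parts else MultiPolygon([]),
        tumor_nests=union_polygons(tumor_parts) if tumor_parts else MultiPolygon([]),
        exclusions=exclusions,
        tls_candidates=tls_list,
        metadata=dict(meta.get("metadata", {})),
        pixel_size=float(pixel_size),
    )


# ---------------------------------------------------------------------------
# tabular inputs


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a long-format cell table (x_um, y_um, marker, positive) to wide.

    Returns one row per cell with boolean positivity columns per marker.
    Rows sharing identical coordinates (or an explicit ``cell_id``) are one
    cell measured for several markers.
    """
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "marker", "positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cell table missing columns {sorted(missing)}")
    key = "cell_id" if "cell_id" in df.columns else ["x_um", "y_um"]
    wide = (
        df.assign(positive=df["positive"].astype(bool))
        .pivot_table(index=key, columns="marker", values="positive", aggfunc="max")
        .fillna(False)
        .astype(bool)
        .reset_index()
    )
    if "cell_id" in df.columns:
        coords = df.groupby("cell_id")[["x_um", "y_um"]].first().reset_index()
        wide = wide.merge(coords, on="cell_id")
    wide.columns.name = None
    return wide


def read_cohort_metadata(path: str | Path) -> dict[str, dict]:
    """Read the cohort metadata CSV into a sample_id -> record map.

    Stage/site values are validated against the controlled vocabulary;
    unknown values pass through with a warning. Duplicate sample ids are a
    hard error.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata must have a sample_id column")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample_id values: {dupes}")
    records: dict[str, dict] = {}
    for _, row in df.iterrows():
        rec = {k: v for k, v in row.items() if k != "sample_id" and pd.notna(v)}
        stage = rec.get("stage")
        if stage is not None and stage not in STAGES:
            warnings.warn(f"{path}: unknown stage {stage!r} for {row['sample_id']}")
        site = rec.get("site")
        if site is not None and site not in SITES:
            warnings.warn(f"{path}: unknown site {site!r} for {row['sample_id']}")
        records[str(row["sample_id"])] = rec
    return records
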