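"""Domain model for annotated tissue scenes.

All geometry is held in millimeter coordinates (image convention: y grows
downward; every metric computed here is orientation independent). A scene
bundles the analyzable tissue region, the tumor nests, exclusion regions
(necrosis, ulceration, hemorrhage, non-infiltrated fat) and the candidate
tertiary lymphoid structures (TLS) with their marker profiles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

#: The six TLS-defining markers measured per candidate structure.
MARKERS = (
    "CD20_aggregate",
    "CXCL13",
    "CD4",
    "CD21_network",
    "CD23_network",
    "BCL6",
)

EXCLUSION_CATEGORIES = frozenset(
    {"necrosis", "ulceration", "hemorrhage", "non_infiltrated_fat"}
)

STAGES = ("primary", "early_met", "late_met")
SITES = ("skin", "lymph_node", "lung", "brain", "nerve", "kidney", "bone", "bladder")


class PhenotypeLabel(str, enum.Enum):
    """TLS maturation phenotype.

    EARLY: dense CD20+ B-cell aggregate with CXCL13+ cells, no follicular
    dendritic cell (FDC) network. PRIMARY_FOLLICULAR: adds CD4+ T cells and a
    CD21+ (CD23-, BCL6-) immature FDC network. SECONDARY_FOLLICULAR_*:
    additionally a CD23+ mature FDC network, with or without BCL6+ lymphatic
    cells in the germinal center.
    """

    EARLY = "EARLY"
    PRIMARY_FOLLICULAR = "PRIMARY_FOLLICULAR"
    SECONDARY_FOLLICULAR_BCL6NEG = "SECONDARY_FOLLICULAR_BCL6NEG"
    SECONDARY_FOLLICULAR_BCL6POS = "SECONDARY_FOLLICULAR_BCL6POS"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Phenotypes carrying a germinal center.
SECONDARY_PHENOTYPES = (
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG,
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS,
)


def as_multipolygon(geom: Optional[BaseGeometry]) -> MultiPolygon:
    """Coerce any shapely geometry to a MultiPolygon (dropping non-areal parts)."""
    if geom is None or geom.is_empty:
        return MultiPolygon([])
    if isinstance(geom, MultiPolygon):
        return geom
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return MultiPolygon(polys)


def union_polygons(geoms: Iterable[BaseGeometry]) -> MultiPolygon:
    return as_multipolygon(unary_union(list(geoms)))


@dataclass
class MarkerProfile:
    """Per-marker positivity fractions for one TLS candidate.

    ``fractions[m]`` is the fraction of object area (or of cells within the
    outline) positive for marker ``m``; derived booleans come from comparing
    against the per-marker thresholds in :class:`~tlsquant.config.ClassifierConfig`.
    """

    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, f in self.fractions.items():
            if m not in MARKERS:
                raise ValueError(f"unknown marker {m!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction for {m} out of [0,1]: {f}")

    def fraction(self, marker: str) -> float:
        return float(self.fractions.get(marker, 0.0))

    def positive(self, marker: str, thresholds: Mapping[str, float]) -> bool:
        return self.fraction(marker) >= thresholds[marker]

    def booleans(self, thresholds: Mapping[str, float]) -> dict[str, bool]:
        return {m: self.positive(m, thresholds) for m in MARKERS}


@dataclass
class ExclusionRegion:
    """Region removed from the analyzable tissue area."""

    polygon: BaseGeometry
    category: str

    def __post_init__(self) -> None:
        if self.category not in EXCLUSION_CATEGORIES:
            raise ValueError(
                f"exclusion category {self.category!r} not in {sorted(EXCLUSION_CATEGORIES)}"
            )


@dataclass
class TLSObject:
    """One candidate lymphoid structure."""

    tls_id: str
    outline: BaseGeometry
    markers: MarkerProfile = field(default_factory=MarkerProfile)
    gc_region: Optional[BaseGeometry] = None
    gc_bcl6_status: Optional[str] = None  # "positive" | "negative"
    phenotype: Optional[PhenotypeLabel] = None
    band_key: Optional[tuple] = None  # (compartment, inner, outer) once assigned

    @property
    def area(self) -> float:
        return float(self.outline.area)

    def validate(self) -> None:
        if self.outline.area <= 0:
            raise ValueError(f"TLS {self.tls_id}: outline has zero area")
        if self.gc_region is not None:
            overhang = self.gc_region.difference(self.outline.buffer(1e-9)).area
            if overhang > 1e-9:
                raise ValueError(f"TLS {self.tls_id}: gc_region not within outline")
        if self.gc_bcl6_status not in (None, "positive", "negative"):
            raise ValueError(f"TLS {self.tls_id}: bad gc_bcl6_status")


@dataclass
class TissueScene:
    """Calibrated per-sample geometry in mm coordinates."""

    sample_id: str
    tissue: MultiPolygon
    tumor_nests: MultiPolygon
    exclusions: list[ExclusionRegion] = field(default_factory=list)
    tls_candidates: list[TLSObject] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    pixel_size: Optional[float] = None  # micrometers per pixel of the source image

    def validate(self, snap_tol_mm: float = 1e-6) -> None:
        """Check scene invariants; raises ValueError on violation."""
        if self.tissue.is_empty or self.tissue.area <= 0:
            raise ValueError(f"{self.sample_id}: empty tissue region")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError(f"{self.sample_id}: pixel_size must be > 0")
        overhang = self.tumor_nests.difference(self.tissue.buffer(snap_tol_mm)).area
        if overhang > snap_tol_mm:
            raise ValueError(
                f"{self.sample_id}: tumor nests extend {overhang:.3g} mm^2 outside tissue"
            )
        for tls in self.tls_candidates:
            tls.validate()
            if not tls.outline.intersects(self.tissue):
                raise ValueError(
                    f"{self.sample_id}: TLS {tls.tls_id} does not intersect tissue"
                )

    @property
    def exclusion_union(self) -> MultiPolygon:
        return union_polygons([e.polygon for e in self.exclusions])

    @property
    def analyzable_tissue(self) -> MultiPolygon:
        """Tissue minus exclusion regions."""
        return as_multipolygon(self.tissue.difference(self.exclusion_union))


# ---------------------------------------------------------------------------
# Band model (filled in by tlsquant.bands)


@dataclass
class Band:
    """One distance band relative to the invasive tumor front.

    Distances are Euclidean, in mm, with half-open intervals (inner, outer]
    so the front itself (d = 0) belongs to no band and a point at exactly
    k mm belongs to band k. ``outer`` may be ``math.inf`` for the
    intratumoral ">1 mm" band.
    """

    compartment: str  # "INTRA" | "EXTRA"
    inner_mm: float
    outer_mm: float
    geometry: MultiPolygon = field(default_factory=lambda: MultiPolygon([]))
    analyzable_area: float = 0.0

    def __post_init__(self) -> None:
        if self.compartment not in ("INTRA", "EXTRA"):
            raise ValueError(f"bad compartment {self.compartment!r}")
        if not (0 <= self.inner_mm < self.outer_mm):
            raise ValueError("need 0 <= inner < outer")

    @property
    def key(self) -> tuple:
        return (self.compartment, self.inner_mm, self.outer_mm)

    @property
    def label(self) -> str:
        outer = "inf" if math.isinf(self.outer_mm) else f"{self.outer_mm:g}"
        return f"{self.compartment}({self.inner_mm:g},{outer}]"

    def sort_key(self) -> tuple:
        """Ordering from most intratumoral outward (used for tie-breaking)."""
        if self.compartment == "INTRA":
            return (0, -self.inner_mm)
        return (1, self.inner_mm)


@dataclass
class BandTable:
    """Partition of the analyzable tissue of one sample into distance bands."""

    sample_id: str
    bands: list[Band]
    beyond_area: float = 0.0  # tissue beyond the outermost EXTRA band
    front_length: float = 0.0  # invasive front length, mm (reference only)

    @property
    def total_analyzable_area(self) -> float:
        return sum(b.analyzable_area for b in self.bands) + self.beyond_area

    def band_for_key(self, key: tuple) -> Band:
        for b in self.bands:
            if b.key == key:
                return b
        raise KeyError(key)
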