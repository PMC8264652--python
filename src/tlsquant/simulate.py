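"""Synthetic tissue scenes with known ground truth.

Each scenario places TLS by independent Poisson counts per (phenotype, band)
with mean lambda * band_area, locations uniform within the band, outlines as
jittered discs. Marker fractions are drawn to satisfy the phenotype decision
table, then perturbed across their thresholds with probability
``marker_noise``. With a fixed seed, generation is bitwise reproducible;
per-sample substreams come from ``SeedSequence([seed, sample_index])`` so
output is independent of generation order.

The two named scenarios emulate the qualitative spatial statistics of
melanoma cohorts: ``primary_like`` is sparse, early-TLS-dominated and
enriched intratumorally within 1 mm of the invasive front; ``metastasis_like``
is denser, secondary-follicular-enriched and peaks extratumorally within
1 mm. A Poisson process cannot reproduce the patient-level overdispersion of
real cohorts (see docs/methods.md); band-profile shapes and the stated
intensities are what the defaults encode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .bands import build_bands, derive_tumor_region
from .config import ClassifierConfig, QuantConfig
from .scene import (
    ExclusionRegion,
    MarkerProfile,
    PhenotypeLabel,
    TissueScene,
    TLSObject,
    as_multipolygon,
)

log = logging.getLogger(__name__)

INTRA_1 = ("INTRA", 0.0, 1.0)
INTRA_BEYOND = ("INTRA", 1.0, math.inf)
EXTRA = [("EXTRA", float(k), float(k + 1)) for k in range(6)]

#: Marker booleans that realize each phenotype's ground truth profile.
PHENOTYPE_PROFILES: dict[PhenotypeLabel, dict[str, bool]] = {
    PhenotypeLabel.EARLY: dict(
        CD20_aggregate=True, CXCL13=True, CD4=False,
        CD21_network=False, CD23_network=False, BCL6=False,
    ),
    PhenotypeLabel.PRIMARY_FOLLICULAR: dict(
        CD20_aggregate=True, CXCL13=True, CD4=True,
        CD21_network=True, CD23_network=False, BCL6=False,
    ),
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG: dict(
        CD20_aggregate=True, CXCL13=True, CD4=True,
        CD21_network=True, CD23_network=True, BCL6=False,
    ),
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS: dict(
        CD20_aggregate=True, CXCL13=True, CD4=True,
        CD21_network=True, CD23_network=True, BCL6=True,
    ),
}


def primary_like_intensity() -> dict[PhenotypeLabel, dict[tuple, float]]:
    """Expected TLS per mm^2 per band: sparse, early-dominated, intratumoral
    <= 1 mm bias with a decaying extratumoral tail."""
    early = {INTRA_1: 0.20, INTRA_BEYOND: 0.03,
             EXTRA[0]: 0.08, EXTRA[1]: 0.03, EXTRA[2]: 0.015,
             EXTRA[3]: 0.008, EXTRA[4]: 0.004, EXTRA[5]: 0.002}
    return {
        PhenotypeLabel.EARLY: early,
        PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG: {INTRA_1: 0.01, EXTRA[0]: 0.02},
        PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS: {EXTRA[0]: 0.005},
    }


def metastasis_like_intensity() -> dict[PhenotypeLabel, dict[tuple, float]]:
    """Denser cohort with secondary follicular TLS peaking extratumorally
    within 1 mm (0.30/mm^2 pooled over BCL6 status in the (0,1] band)."""
    return {
        PhenotypeLabel.EARLY: {
            INTRA_1: 0.15, INTRA_BEYOND: 0.04,
            EXTRA[0]: 0.30, EXTRA[1]: 0.10, EXTRA[2]: 0.05,
            EXTRA[3]: 0.03, EXTRA[4]: 0.02, EXTRA[5]: 0.01,
        },
        PhenotypeLabel.PRIMARY_FOLLICULAR: {EXTRA[0]: 0.02},
        PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG: {
            INTRA_1: 0.03, INTRA_BEYOND: 0.01,
            EXTRA[0]: 0.25, EXTRA[1]: 0.08, EXTRA[2]: 0.02, EXTRA[3]: 0.01,
        },
        PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS: {
            EXTRA[0]: 0.05, EXTRA[1]: 0.01,
        },
    }


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_samples: int = 10
    scenario: str = "custom"  # primary_like | metastasis_like | custom
    tissue_extent: tuple[float, float] = (20.0, 20.0)  # mm
    tumor_shape: str = "disc"  # disc | blob
    tumor_irregularity: float = 0.25  # blob radial jitter, fraction of radius
    tumor_radius: float = 3.0  # mm
    intensity: dict = field(default_factory=dict)  # lambda[phenotype][band_key]
    tls_radius_range: tuple[float, float] = (0.05, 0.25)  # mm
    marker_noise: float = 0.05
    exclusion_fraction: float = 0.0  # fraction of tumor area turned to necrosis
    seed: int = 0
    stage: Optional[str] = None  # metadata written for the cohort
    site: Optional[str] = None
    cohort_label: Optional[str] = None  # sample-id prefix (defaults to scenario)

    def __post_init__(self) -> None:
        if self.scenario == "primary_like":
            self.intensity = self.intensity or primary_like_intensity()
            self.stage = self.stage or "primary"
            self.site = self.site or "skin"
        elif self.scenario == "metastasis_like":
            self.intensity = self.intensity or metastasis_like_intensity()
            self.stage = self.stage or "late_met"
            self.site = self.site or "lymph_node"
        for per_band in self.intensity.values():
            if any(lam < 0 for lam in per_band.values()):
                raise ValueError("intensities must be >= 0")
        if not (0 <= self.marker_noise <= 1):
            raise ValueError("marker_noise must be in [0,1]")
        max_extra = max((b[2] for per in self.intensity.values() for b in per
                         if b[0] == "EXTRA"), default=0.0)
        clearance = min(self.tissue_extent) / 2.0 - self.tumor_radius
        if clearance < max_extra:
            raise ValueError(
                f"tumor must clear the tissue edge by >= {max_extra} mm for the "
                f"requested extratumoral bands (got {clearance:.2f} mm)"
            )


def _tumor_polygon(spec: CohortSpec, rng: np.random.Generator) -> Polygon:
    cx, cy = spec.tissue_extent[0] / 2.0, spec.tissue_extent[1] / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, 73)[:-1]
    r = np.full_like(theta, spec.tumor_radius)
    if spec.tumor_shape == "blob" and spec.tumor_irregularity > 0:
        # smooth radial perturbation from a few random Fourier modes
        for k in (2, 3, 5):
            amp = spec.tumor_irregularity * spec.tumor_radius * rng.uniform(0.1, 0.5)
            r = r + amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        r = np.clip(r, 0.3 * spec.tumor_radius, None)
    xy = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return Polygon(xy)


def _sample_point_in(geom, rng: np.random.Generator, max_tries: int = 10_000) -> Point:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(max_tries):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if geom.contains(p):
            return p
    raise RuntimeError("rejection sampling failed; band geometry degenerate?")


def _jittered_disc(center: Point, radius: float, rng: np.random.Generator) -> Polygon:
    n = int(rng.integers(8, 25))
    # evenly spaced angles with bounded jitter keep the polygon star-shaped
    # about the center, so a concentric germinal center stays inside
    step = 2 * np.pi / n
    theta = np.arange(n) * step + rng.uniform(-0.35, 0.35, size=n) * step
    r = radius * rng.uniform(0.75, 1.25, size=n)
    xy = np.column_stack([center.x + r * np.cos(theta), center.y + r * np.sin(theta)])
    poly = Polygon(xy)
    if not poly.is_valid or poly.area <= 0:
        poly = Point(center).buffer(radius, quad_segs=8)
    return poly


def _marker_fractions(
    profile: dict[str, bool], thresholds: dict[str, float],
    noise: float, rng: np.random.Generator,
) -> dict[str, float]:
    fractions = {}
    for marker, truth in profile.items():
        positive = truth
        if noise > 0 and rng.uniform() < noise:
            positive = not positive
        thr = thresholds[marker]
        if positive:
            fractions[marker] = float(rng.uniform(min(thr * 1.2, 1.0), min(thr + 0.4, 1.0)))
        else:
            fractions[marker] = float(rng.uniform(0.0, thr * 0.5))
    return fractions


def generate_scene(
    spec: CohortSpec,
    sample_index: int,
    classifier: Optional[ClassifierConfig] = None,
) -> tuple[TissueScene, pd.DataFrame]:
    """Generate one scene plus its ground-truth table.

    Returns ``(scene, truth)`` where ``truth`` has one row per placed TLS:
    tls_id, phenotype, band compartment/inner/outer, center coordinates.
    Bands with zero area contribute zero TLS (with a warning when their
    requested intensity was positive).
    """
    classifier = classifier or ClassifierConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(sample_index)]))
    sample_id = f"{spec.cohort_label or spec.scenario or 'custom'}_{sample_index:03d}"

    w, h = spec.tissue_extent
    tissue = as_multipolygon(box(0.0, 0.0, w, h))
    tumor = as_multipolygon(_tumor_polygon(spec, rng))
    scene = TissueScene(
        sample_id=sample_id, tissue=tissue, tumor_nests=tumor,
        metadata={k: v for k, v in (("stage", spec.stage), ("site", spec.site)) if v},
    )

    exclusions: list[ExclusionRegion] = []
    if spec.exclusion_fraction > 0:
        # a necrotic disc at the tumor center with the requested area share
        r_necro = math.sqrt(spec.exclusion_fraction * tumor.area / math.pi)
        necro = Point(tumor.centroid).buffer(r_necro, quad_segs=16)
        exclusions.append(ExclusionRegion(as_multipolygon(necro.intersection(tumor)), "necrosis"))
    scene.exclusions = exclusions

    region = derive_tumor_region(scene, closing_radius_mm=0.0)
    table = build_bands(scene, tumor_region=region,
                        radii=[b[2] for b in EXTRA],
                        config=QuantConfig(closing_radius_mm=0.0))

    tls_list: list[TLSObject] = []
    truth_rows = []
    for phenotype in sorted(spec.intensity, key=lambda p: p.value):
        for band_key in sorted(spec.intensity[phenotype]):
            lam = spec.intensity[phenotype][band_key]
            if lam == 0:
                continue
            band = table.band_for_key(band_key)
            if band.analyzable_area <= 0:
                log.warning("%s: band %s has zero area; 0 TLS placed", sample_id, band.label)
                continue
            n = int(rng.poisson(lam * band.analyzable_area))
            for _ in range(n):
                center = _sample_point_in(band.geometry, rng)
                radius = float(rng.uniform(*spec.tls_radius_range))
                outline = _jittered_disc(center, radius, rng).intersection(tissue)
                fractions = _marker_fractions(
                    PHENOTYPE_PROFILES[phenotype], classifier.thresholds,
                    spec.marker_noise, rng,
                )
                tls = TLSObject(
                    tls_id=f"{sample_id}_tls_{len(tls_list)}",
                    outline=as_multipolygon(outline),
                    markers=MarkerProfile(fractions),
                )
                if phenotype in (PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG,
                                 PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS):
                    # concentric germinal center at 30% of the outline area
                    import shapely.affinity as aff

                    f = math.sqrt(0.30)
                    tls.gc_region = as_multipolygon(aff.scale(
                        tls.outline, xfact=f, yfact=f, origin=(center.x, center.y)))
                tls_list.append(tls)
                truth_rows.append(dict(
                    sample_id=sample_id, tls_id=tls.tls_id,
                    phenotype=phenotype.value, compartment=band_key[0],
                    inner_mm=band_key[1], outer_mm=band_key[2],
                    x_mm=center.x, y_mm=center.y, radius_mm=radius,
                ))

    scene.tls_candidates = tls_list
    scene.validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "tls_id", "phenotype", "compartment",
                 "inner_mm", "outer_mm", "x_mm", "y_mm", "radius_mm"],
    )
    return scene, truth


def generate_cohort(
    spec_primary: CohortSpec,
    spec_met: Optional[CohortSpec] = None,
    out_dir: Optional[str | Path] = None,
) -> tuple[list[TissueScene], pd.DataFrame, pd.DataFrame]:
    """Generate a two-arm (or single-arm) cohort; optionally write to disk.

    Returns (scenes, metadata table, ground-truth table). With ``out_dir``
    set, writes one GeoJSON per scene plus ``metadata.csv`` and
    ``ground_truth.csv``; regeneration under the same seeds is bit-identical.
    """
    scenes: list[TissueScene] = []
    meta_rows = []
    truths = []
    specs = [s for s in (spec_primary, spec_met) if s is not None]
    for spec in specs:
        if spec.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for i in range(spec.n_samples):
            scene, truth = generate_scene(spec, i)
            scenes.append(scene)
            truths.append(truth)
            meta_rows.append(dict(sample_id=scene.sample_id,
                                  stage=spec.stage, site=spec.site))
    metadata = pd.DataFrame(meta_rows)
    truth = pd.concat(truths, ignore_index=True)
    if out_dir is not None:
        from .io import write_scene

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for scene in scenes:
            write_scene(scene, out / f"{scene.sample_id}.geojson")
        metadata.to_csv(out / "metadata.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
    return scenes, metadata, truth
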