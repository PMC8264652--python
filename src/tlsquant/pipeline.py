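"""End-to-end quantification over a directory of annotated scenes.

Deterministic given (inputs, config): reads each scene, derives the tumor
compartment and distance bands, classifies and band-assigns every TLS
candidate, and writes tidy density, band-area and classification-audit
tables. Per-sample failures are isolated (sample skipped with a logged
reason) unless ``strict`` is set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .bands import assign_tls_to_band, build_bands, derive_tumor_region
from .config import QuantConfig
from .density import quantify_cohort, quantify_sample
from .io import read_cohort_metadata, read_scene
from .phenotype import classification_audit, classify_scene
from .scene import BandTable, TissueScene

log = logging.getLogger(__name__)

SCENE_SUFFIXES = (".geojson", ".json", ".tif", ".tiff", ".png")


@dataclass
class SampleResult:
    scene: TissueScene
    bands: BandTable
    records: pd.DataFrame


@dataclass
class PipelineResult:
    samples: dict[str, SampleResult] = field(default_factory=dict)
    records: Optional[pd.DataFrame] = None
    band_areas: Optional[pd.DataFrame] = None
    audit: Optional[pd.DataFrame] = None
    skipped: dict[str, str] = field(default_factory=dict)


def quantify_scene(scene: TissueScene, config: Optional[QuantConfig] = None) -> SampleResult:
    """Run classification, banding, assignment and quantification on one scene."""
    config = config or QuantConfig()
    classify_scene(scene.tls_candidates, config.classifier)
    tumor = derive_tumor_region(scene, config.closing_radius_mm)
    bands = build_bands(scene, tumor_region=tumor, radii=config.radii, config=config)
    excl = scene.exclusion_union
    n_dropped = 0
    for tls in scene.tls_candidates:
        key = assign_tls_to_band(tls, bands, excl, config.exclusion_drop_fraction)
        n_dropped += key[0] == "DROPPED"
    records = quantify_sample(scene, bands)
    log.info(
        "%s: %d candidates, %d dropped (exclusions), front %.2f mm",
        scene.sample_id, len(scene.tls_candidates), n_dropped, bands.front_length,
    )
    return SampleResult(scene=scene, bands=bands, records=records)


def band_area_table(bands: BandTable) -> pd.DataFrame:
    rows = [
        dict(sample_id=bands.sample_id, compartment=b.compartment,
             inner_mm=b.inner_mm,
             outer_mm=(math.inf if math.isinf(b.outer_mm) else b.outer_mm),
             analyzable_area_mm2=b.analyzable_area)
        for b in bands.bands
    ]
    rows.append(dict(sample_id=bands.sample_id, compartment="BEYOND",
                     inner_mm=float("nan"), outer_mm=float("nan"),
                     analyzable_area_mm2=bands.beyond_area))
    return pd.DataFrame(rows)


def run_pipeline(
    input_dir: str | Path,
    metadata: Optional[str | Path | Mapping[str, Mapping]] = None,
    config: Optional[QuantConfig] = None,
    out_dir: Optional[str | Path] = None,
    strict: bool = False,
) -> PipelineResult:
    """Quantify every scene file in ``input_dir``; optionally write CSVs.

    ``metadata`` may be a CSV path or an already-parsed sample->record map
    (it is not required for quantification, only carried through for the
    comparison step). Outputs: density.csv, band_areas.csv, audit.csv.
    """
    config = config or QuantConfig()
    input_dir = Path(input_dir)
    paths = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in SCENE_SUFFIXES and not p.name.endswith(".tif.json")
        and p.stem + p.suffix != "metadata.csv"
    )
    # sidecar jsons of masks are not scenes
    mask_stems = {p.stem for p in paths if p.suffix.lower() in (".tif", ".tiff", ".png")}
    paths = [p for p in paths if not (p.suffix.lower() == ".json" and p.stem in mask_stems)]
    if not paths:
        raise FileNotFoundError(f"no scene files in {input_dir}")

    if isinstance(metadata, (str, Path)):
        metadata = read_cohort_metadata(metadata)

    result = PipelineResult()
    for path in paths:
        try:
            scene = read_scene(path, config=config)
            sample = quantify_scene(scene, config)
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            if strict:
                raise
            log.error("skipping %s: %s", path.name, exc)
            result.skipped[path.name] = str(exc)
            continue
        result.samples[scene.sample_id] = sample

    if not result.samples:
        raise RuntimeError("no sample could be processed")
    result.records = quantify_cohort([s.records for s in result.samples.values()])
    result.band_areas = pd.concat(
        [band_area_table(s.bands) for s in result.samples.values()], ignore_index=True
    )
    audits = []
    for sid, s in result.samples.items():
        a = classification_audit(s.scene.tls_candidates, config.classifier)
        a.insert(0, "sample_id", sid)
        audits.append(a)
    result.audit = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.records.to_csv(out / "density.csv", index=False)
        result.band_areas.to_csv(out / "band_areas.csv", index=False)
        result.audit.to_csv(out / "audit.csv", index=False)
    return result
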