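"""Configuration objects and (de)serialization.

A single nested YAML file drives the whole pipeline: marker positivity
thresholds, perimeter radii, morphological closing radius, annotation class
name mapping and the random seed. Configs round-trip through
``save_config``/``load_config`` unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .scene import MARKERS


def _default_thresholds() -> dict[str, float]:
    # Fraction of object area/cells that must be positive for the marker to
    # count as present. The B-cell aggregate itself must dominate the object;
    # network/expression markers only need a detectable compartment.
    thr = {m: 0.10 for m in MARKERS}
    thr["CD20_aggregate"] = 0.50
    return thr


@dataclass
class ClassifierConfig:
    """Parameters of TLS detection and phenotype classification."""

    thresholds: dict[str, float] = field(default_factory=_default_thresholds)
    min_aggregate_area: float = 0.005  # mm^2; smaller objects stay unclassified
    min_cd20_cells: int = 50  # detection mode only
    link_radius_um: float = 30.0  # fixed-radius linkage for CD20+ cell clustering
    cell_disc_radius_um: float = 20.0  # disc drawn around each member cell
    cxcl13_collar_um: float = 50.0  # CXCL13 measured in outline + collar
    gc_default_fraction: float = 0.30  # GC area fallback as fraction of outline

    def __post_init__(self) -> None:
        for m, t in self.thresholds.items():
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold for {m} must be in (0,1]: {t}")
        if not self.min_aggregate_area > 0:
            raise ValueError("min_aggregate_area must be > 0")


def _default_class_map() -> dict[str, str]:
    # QuPath annotation class name -> scene layer. Keys are matched
    # case-insensitively on read.
    return {
        "Tissue": "tissue",
        "Tumor": "tumor",
        "TLS": "tls",
        "Necrosis": "necrosis",
        "Ulceration": "ulceration",
        "Hemorrhage": "hemorrhage",
        "Fat": "non_infiltrated_fat",
    }


@dataclass
class QuantConfig:
    """Top-level pipeline configuration."""

    radii: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    closing_radius_mm: float = 0.5
    edge_tolerance_mm: float = 0.05
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    class_map: dict[str, str] = field(default_factory=_default_class_map)
    exclusion_drop_fraction: float = 0.5  # drop TLS with >= this share in exclusions
    min_polygon_area_mm2: float = 1e-6  # degenerate-annotation cutoff after repair
    pixel_size_um: Optional[float] = None  # fallback calibration for uncalibrated files
    seed: int = 0
    out_dir: str = "tlsquant_out"

    def __post_init__(self) -> None:
        r = list(self.radii)
        if not r or any(b <= a for a, b in zip(r, r[1:])) or r[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if not self.closing_radius_mm >= 0:
            raise ValueError("closing_radius_mm must be >= 0")
        if not self.edge_tolerance_mm >= 0:
            raise ValueError("edge_tolerance_mm must be >= 0")


def config_to_dict(cfg: QuantConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> QuantConfig:
    d = dict(d)
    cls = d.pop("classifier", None)
    cfg = QuantConfig(**d) if d else QuantConfig()
    if cls is not None:
        cfg.classifier = ClassifierConfig(**cls)
    return cfg


def save_config(cfg: QuantConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str | Path) -> QuantConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
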