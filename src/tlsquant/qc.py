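"""QC overlay rendering: tumor compartment, front, bands and classified TLS."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath

from .bands import BEYOND, DROPPED
from .pipeline import SampleResult
from .scene import PhenotypeLabel, as_multipolygon

PHENOTYPE_COLORS = {
    PhenotypeLabel.EARLY: "#1f77b4",
    PhenotypeLabel.PRIMARY_FOLLICULAR: "#2ca02c",
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG: "#ff7f0e",
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS: "#d62728",
    PhenotypeLabel.UNCLASSIFIED: "#7f7f7f",
}


def _poly_patch(geom, **kwargs) -> Optional[PathPatch]:
    mp = as_multipolygon(geom)
    if mp.is_empty:
        return None
    vertices, codes = [], []
    for poly in mp.geoms:
        for ring in [poly.exterior, *poly.interiors]:
            pts = list(ring.coords)
            vertices.extend(pts)
            codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(pts) - 2) + [MplPath.CLOSEPOLY])
    return PathPatch(MplPath(vertices, codes), **kwargs)


def render_qc(sample: SampleResult, path: str | Path, summary_path: Optional[str | Path] = None) -> None:
    """Write an overlay figure (PNG/PDF by extension) and a text summary.

    Shows tissue, bands (alternating shading), tumor compartment, invasive
    front, exclusion regions, and TLS colored by phenotype; TLS dropped into
    exclusions are hatched.
    """
    scene, bands = sample.scene, sample.bands
    fig, ax = plt.subplots(figsize=(7, 7))
    for geom, kw in [(scene.tissue, dict(facecolor="#fff8e1", edgecolor="k", lw=0.8))]:
        p = _poly_patch(geom, **kw)
        if p:
            ax.add_patch(p)
    for i, band in enumerate(bands.bands):
        shade = "#c8e6c9" if band.compartment == "EXTRA" else "#d7ccc8"
        p = _poly_patch(band.geometry, facecolor=shade,
                        alpha=0.35 + 0.1 * (i % 2), edgecolor="none")
        if p:
            ax.add_patch(p)
    for ex in scene.exclusions:
        p = _poly_patch(ex.polygon, facecolor="none", edgecolor="k", hatch="////", lw=0.5)
        if p:
            ax.add_patch(p)
    for tls in scene.tls_candidates:
        dropped = tls.band_key == DROPPED
        color = PHENOTYPE_COLORS.get(tls.phenotype, "#7f7f7f")
        p = _poly_patch(tls.outline, facecolor=color, edgecolor="k", lw=0.3,
                        hatch="xxx" if dropped else None, alpha=0.9)
        if p:
            ax.add_patch(p)

    minx, miny, maxx, maxy = scene.tissue.bounds
    ax.set_xlim(minx - 0.5, maxx + 0.5)
    ax.set_ylim(maxy + 0.5, miny - 0.5)  # image convention: y down
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"{scene.sample_id}  front {bands.front_length:.1f} mm")
    fig.savefig(path, dpi=150)
    plt.close(fig)

    if summary_path is not None:
        n_by = {}
        for tls in scene.tls_candidates:
            label = tls.phenotype.value if tls.phenotype else "unclassified"
            n_by[label] = n_by.get(label, 0) + 1
        dropped = sum(1 for t in scene.tls_candidates if t.band_key == DROPPED)
        beyond = sum(1 for t in scene.tls_candidates if t.band_key == BEYOND)
        lines = [
            f"sample: {scene.sample_id}",
            f"tissue area: {scene.tissue.area:.2f} mm^2",
            f"analyzable area: {bands.total_analyzable_area:.2f} mm^2",
            f"front length: {bands.front_length:.2f} mm",
            f"candidates: {len(scene.tls_candidates)} "
            f"(dropped {dropped}, beyond bands {beyond})",
        ]
        lines += [f"  {k}: {v}" for k, v in sorted(n_by.items())]
        lines += [f"band {b.label}: {b.analyzable_area:.3f} mm^2" for b in bands.bands]
        Path(summary_path).write_text("\n".join(lines) + "\n")
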