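"""Distance bands around the invasive front and density normalization.

A 3 mm disc tumor sits centered in a 20 x 20 mm tissue section. The
extratumoral band (k-1, k] is then the annulus between radii 3+k-1 and 3+k,
so band areas have a closed form and the per-band TLS densities (count per
mm^2 analyzable tissue) can be checked by hand.
"""

import math

from shapely.geometry import MultiPolygon, Point, box

from tlsquant import (
    MarkerProfile,
    QuantConfig,
    TissueScene,
    TLSObject,
    quantify_scene,
)

early = {"CD20_aggregate": 0.8, "CXCL13": 0.4}
tls = [
    TLSObject(f"t{i}", Point(13.5, 9.0 + 0.7 * i).buffer(0.1), MarkerProfile(early))
    for i in range(3)  # three TLS ~0.5 mm outside the front
]
scene = TissueScene(
    "demo",
    tissue=MultiPolygon([box(0, 0, 20, 20)]),
    tumor_nests=MultiPolygon([Point(10, 10).buffer(3.0, quad_segs=128)]),
    tls_candidates=tls,
)
sample = quantify_scene(scene, QuantConfig(closing_radius_mm=0.0))

print("band areas (mm^2), analytic annulus in parentheses:")
for band in sample.bands.bands:
    if band.compartment == "EXTRA":
        k = band.outer_mm
        analytic = math.pi * ((3 + k) ** 2 - (3 + k - 1) ** 2)
        print(f"  {band.label:14s} {band.analyzable_area:7.2f}  ({analytic:.2f})")
    else:
        print(f"  {band.label:14s} {band.analyzable_area:7.2f}")

rec = sample.records
row = rec[(rec.level == "band") & (rec.band_label == "EXTRA(0,1]")
          & (rec.phenotype == "EARLY")].iloc[0]
print(f"\n3 early TLS in EXTRA(0,1]: density {row.count_density:.4f} /mm^2 "
      f"(= 3 / {row.analyzable_area_mm2:.2f}), area fraction {row.area_fraction:.5f}")
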