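# Methods

This note documents the models, conventions and defaults behind
`tlsquant`, the choices that were genuinely open, and what the synthetic
cohorts do and do not demonstrate.

## Scene model and calibration

All geometry lives in millimeter coordinates under the image convention
(y down); every reported metric is an area or count ratio and therefore
orientation-independent. GeoJSON coordinates are interpreted as pixel
units and scaled by the mandatory `pixel_size_um` calibration (file
property or config fallback); missing calibration is a hard error rather
than a guessed default, because every downstream number carries units of
mm⁻². Invalid polygons are repaired with `make_valid`, which decomposes
self-intersecting outlines into all their areal parts; repaired polygons
below 10⁻⁶ mm² are dropped as degenerate annotations. Label masks are
vectorized by marching squares at the 0.5 iso-level; this chamfers each
convex corner by 1/8 px², keeping areas within 1% of the pixel count for
blobs ≥ 100 px (tested). In a label mask every labeled pixel is tissue —
the tissue layer is traced from the composite foreground, and tumor,
exclusion and TLS labels are nested refinements.

## Phenotype classification

The classifier maps six positivity fractions to one maturation label via
the ordered conjunction table in the README. Two surrogates deserve
comment:

- **Thresholds.** The underlying assay establishes "presence of a network"
  by trained tissue segmentation, which has no single numeric equivalent.
  We expose per-marker fraction thresholds instead (defaults: CD20 0.50 —
  the B-cell aggregate must dominate the object; all others 0.10 — a
  detectable compartment suffices). These defaults are config keys, not
  constants, precisely because they are surrogates.
- **Undefined states.** Profiles with an FDC network but no CD4⁺ T cells,
  or BCL6 without a CD23⁺ mature network, match no defined phenotype and
  stay UNCLASSIFIED rather than being forced into the nearest class. The
  committed 2⁶ truth table freezes this behavior.

Objects below `min_aggregate_area` (default 0.005 mm², configurable; no
canonical minimum exists for "dense aggregate") are never classified.
CXCL13 in detection mode is measured inside the outline plus a 50 µm
collar, because the chemokine is frequently expressed by cells surrounding
rather than inside young aggregates; the collar width is a config key.

Detection from cell tables clusters CD20⁺ centroids by fixed-radius single
linkage (30 µm), keeps clusters of ≥ 50 cells, and takes the union of
20 µm discs around members as the outline. This is a deliberately simple,
deterministic stand-in for trainable segmentation, adequate for centroid
exports.

Secondary follicular TLS without an annotated germinal center get a
concentric GC at 30% of the outline area (config key
`gc_default_fraction`); the BCL6± status mirrors the classification
branch.

## Invasive front and distance bands

- **Tumor compartment** = morphological closing (buffer out/in, default
  radius 0.5 mm, holes filled) of the union of tumor nests, clipped to
  tissue. Closing merges nests separated by narrow stromal septa, so
  intratumoral stroma counts as intratumoral — there is no canonical
  delimitation of intratumoral stroma, and 0.5 mm is our convention
  (config key).
- **Invasive front** = boundary of the tumor compartment minus any part
  within `edge_tolerance_mm` (default 0.05 mm) of the tissue boundary: a
  section cut edge is not a biological front. A zero-length front (tumor
  fills the section) is a hard error instructing exclusion of the sample.
- **Distance** = Euclidean distance to the front, realized by iterated
  buffering of the tumor compartment. Geodesic-within-tissue distance was
  rejected: Euclidean buffers are deterministic, library-supported, and
  directly checkable against a pixel distance transform. Hand-drawn
  expansions in viewer software may differ by small amounts near concave
  corners.
- **Bands** are half-open (k−1, k] mm so the front itself (d = 0) belongs
  to no band and a point at exactly k mm belongs to band k. Extratumoral
  bands default to (0,1] … (5,6]; the intratumoral side is split into
  (0,1] and (1,∞) only, since deeper 1 mm shells are rarely analyzable in
  real material. Bands truncated by the available tissue keep their
  reduced area — the normalization absorbs truncation.
- **Exclusions** (necrosis, ulceration, hemorrhage, non-infiltrated fat)
  are subtracted from every band's analyzable area. The partition
  invariant Σ band areas + beyond-band area = exclusion-corrected tissue
  area is checked on every table (tolerance 10⁻⁶ mm²).
- **Assignment**: a TLS goes to the band holding the larger share of its
  area; exact ties fall to the band containing the centroid, then to the
  more intratumoral band (fixed order, so reruns are identical). The
  larger-share rule is extended across the intra/extratumoral boundary.
  TLS with ≥ 50% of their area inside exclusions are dropped with a logged
  reason; TLS beyond the outermost band land in a "beyond" bucket excluded
  from band statistics.

## Density metrics

Per sample × phenotype × band: TLS count, count density (n per mm²
analyzable area), area fraction (Σ area(outline ∩ band) per mm², which
keeps fractions ≤ 1 and additive across bands even when outlines straddle
band boundaries), and GC BCL6⁺/BCL6⁻ area fractions. Compartment
aggregates pool counts over pooled areas — Σn/ΣA, not the mean of per-band
densities — and the suite asserts the two differ where they should. Bands
with zero analyzable area yield flagged missing densities that statistics
exclude; a count in a zero-area band is an inconsistency and raises.
A sample is TLS-positive iff it retains ≥ 1 classified TLS of any
phenotype; UNCLASSIFIED candidates are tabulated but are not TLS.

## Cohort statistics

All tests are two-sided and operate on one value per sample. Wilcoxon rank
sum uses exact enumeration when n_x + n_y ≤ 12 without ties, otherwise the
normal approximation with tie and continuity correction (the
continuity-corrected approximation tracks the exact law to ~0.02 at
n = 12, tested). Fisher's exact test uses the two-sided point-probability
rule. Benjamini–Hochberg correction is applied within one family per
comparison plan — family boundaries are not canonical, so each report
records its family and size. Identical-constant inputs return p = 1 with a
warning instead of failing. scipy.stats and statsmodels provide the
numerics; tests verify them against independent brute-force enumeration
(all 2×2 tables with N ≤ 30, full rank permutation for n ≤ 10, step-up
recursion on random p-vectors).

## Synthetic cohorts: what they emulate

`generate_scene` places TLS by independent Poisson counts with mean
λ[phenotype][band] · area(band), uniform within the band, as jittered
discs (8–24 vertices, radius 0.05–0.25 mm — realistic TLS diameters of
0.1–0.5 mm). Poisson-per-band, rather than a thinned global process, makes
intensity recovery an exact test: the estimator Σn/ΣA is unbiased for λ
with standard error √(λ/ΣA). Marker fractions are drawn to satisfy the
ground-truth phenotype's conjunction, then flipped across their threshold
with probability `marker_noise` (default 0.05). Seeding: one global seed
expands to per-sample streams via `SeedSequence([seed, sample_index])`, so
generation is bitwise reproducible and order-independent.

Scenario defaults (intensities in TLS/mm²): the **primary-like** arm is
early-dominated with an intratumoral (0,1] peak (0.20) and a decaying
extratumoral tail (0.08 → 0.002), plus traces of secondary follicular TLS;
the **metastasis-like** arm peaks extratumorally within 1 mm (early 0.30,
secondary follicular 0.30 pooled over BCL6 status) and decays outward.
Geometry defaults: 20 × 20 mm tissue, 3 mm disc (or blob) tumor, leaving
≥ 6 mm clearance for the requested extratumoral bands.

**Limitations.** A Poisson process reproduces band-profile shapes and mean
densities, not patient-level dispersion: real cohorts are strongly
zero-inflated (most primary tumors contain no TLS at all while a few
contain dozens), so synthetic prevalence is near 100% per arm and
between-patient variance is Poisson-narrow. Passing tests therefore
demonstrate correctness of the measurement pipeline — classification,
banding, normalization, statistics — under known ground truth, not that
the generator mimics patient-to-patient heterogeneity. The generator also
does not render fluorescence images or simulate cells beyond centroid
tables.

## Numerical choices and problem sizes

- Geometry uses exact vector operations (shapely/GEOS); the pixel
  distance-transform oracle runs at 10 µm resolution, where half-pixel
  discretization keeps band-area deviations well under the 2% assertion.
- The intensity-recovery check uses 200 scenes (3 SE ≈ 8% of λ = 0.30);
  the acceptance script uses 100 scenes for the same estimator.
- The null-calibration simulation draws per-sample band counts directly
  from the generator's Poisson law (500 replicate two-arm cohorts of 20 +
  20 samples) rather than generating 20,000 full scenes; the count model
  is identical, only the geometry — which is constant under the null — is
  factored out.
- Tie-breaks, band ordering and per-sample seed streams are all fixed, so
  the pipeline is a pure function of (inputs, config): output CSVs are
  byte-identical across reruns (tested).
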