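"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles (enumeration,
pixel rasterization) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon


# ---------------------------------------------------------------------------
# statistics


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1)
                        if prob(x) <= p_obs * (1 + 1e-9)))


def bh_step_up(p: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def wilcoxon_exact_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all rank assignments.

    Requires tie-free data. Uses the symmetric-distribution convention
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    nx = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        us.append(sum(combo) - nx * (nx + 1) / 2)
    us = np.asarray(us, dtype=float)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def kruskal_permutation_p(groups, n_perm: int = 100_000, seed: int = 0) -> float:
    """Permutation p-value for the Kruskal-Wallis H statistic."""
    from scipy.stats import kruskal

    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    h_obs = kruskal(*groups)[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if kruskal(*parts)[0] >= h_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# geometry: pixel distance-transform band areas


def pixel_band_areas(scene, radii, px_mm: float = 0.01) -> dict[tuple, float]:
    """Band areas from a per-pixel Euclidean distance transform.

    Rasterizes tissue and tumor at ``px_mm`` resolution, computes the
    distance of every pixel to the tumor boundary with
    ``scipy.ndimage.distance_transform_edt`` and bins pixel counts into the
    same (compartment, inner, outer] bands the vector code produces.
    """
    minx, miny, maxx, maxy = scene.tissue.bounds
    pad = radii[-1] + 2 * px_mm
    nx = int(round((maxx - minx + 2 * pad) / px_mm)) + 1
    ny = int(round((maxy - miny + 2 * pad) / px_mm)) + 1

    def rasterize(mp):
        mask = np.zeros((ny, nx), dtype=bool)
        for poly in getattr(mp, "geoms", [mp]):
            xs, ys = np.asarray(poly.exterior.coords).T
            rr, cc = draw_polygon((ys - miny + pad) / px_mm, (xs - minx + pad) / px_mm,
                                  shape=mask.shape)
            mask[rr, cc] = True
            for ring in poly.interiors:
                xs, ys = np.asarray(ring.coords).T
                rr, cc = draw_polygon((ys - miny + pad) / px_mm, (xs - minx + pad) / px_mm,
                                      shape=mask.shape)
                mask[rr, cc] = False
        return mask

    tissue = rasterize(scene.tissue)
    tumor = rasterize(scene.tumor_nests) & tissue
    excl = np.zeros_like(tissue)
    for ex in scene.exclusions:
        excl |= rasterize(ex.polygon)
    analyzable = tissue & ~excl

    # distances in mm to the tumor boundary, on both sides
    d_out = ndimage.distance_transform_edt(~tumor) * px_mm
    d_in = ndimage.distance_transform_edt(tumor) * px_mm

    areas: dict[tuple, float] = {}
    px_area = px_mm * px_mm
    r1 = radii[0]
    areas[("INTRA", r1, math.inf)] = float(np.sum(tumor & analyzable & (d_in > r1))) * px_area
    areas[("INTRA", 0.0, r1)] = float(np.sum(tumor & analyzable & (d_in <= r1))) * px_area
    prev = 0.0
    for r in radii:
        sel = ~tumor & analyzable & (d_out > prev) & (d_out <= r)
        areas[("EXTRA", prev, r)] = float(np.sum(sel)) * px_area
        prev = r
    return areas
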