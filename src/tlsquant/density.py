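"""Per-sample TLS density, relative-area, prevalence and composition metrics.

Counts and areas of each phenotype are normalized to the analyzable tissue
area (mm^2) of each distance band; compartment-level aggregates pool counts
over pooled areas (sum of counts / sum of areas), not means of per-band
densities. Bands with zero analyzable area yield flagged missing densities,
never a division by zero.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bands import BEYOND, DROPPED
from .scene import BandTable, PhenotypeLabel, TissueScene

#: Phenotypes counted as TLS (UNCLASSIFIED candidates are not TLS).
TLS_PHENOTYPES = (
    PhenotypeLabel.EARLY,
    PhenotypeLabel.PRIMARY_FOLLICULAR,
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6NEG,
    PhenotypeLabel.SECONDARY_FOLLICULAR_BCL6POS,
)
ALL = "ALL"

RECORD_COLUMNS = [
    "sample_id", "phenotype", "level", "compartment", "inner_mm", "outer_mm",
    "band_label", "analyzable_area_mm2", "n_tls", "count_density",
    "area_fraction", "gc_bcl6pos_area_fraction", "gc_bcl6neg_area_fraction",
    "flagged",
]

_PHENOS = list(TLS_PHENOTYPES) + [PhenotypeLabel.UNCLASSIFIED]


def _tally(sample_id: str, members, band) -> dict:
    """Raw sums for one phenotype in one band."""
    n = len(members)
    if band.analyzable_area <= 0 and n > 0:
        raise ValueError(
            f"{sample_id}: {n} TLS assigned to zero-area band {band.label}"
        )
    tls_area = sum(t.outline.intersection(band.geometry).area for t in members)
    gc_pos = gc_neg = 0.0
    for t in members:
        if t.gc_region is not None and not t.gc_region.is_empty:
            a = t.gc_region.intersection(band.geometry).area
            if t.gc_bcl6_status == "positive":
                gc_pos += a
            else:
                gc_neg += a
    return dict(n=n, tls_area=tls_area, gc_pos=gc_pos, gc_neg=gc_neg)


def _row(sample_id, phenotype, level, compartment, inner, outer, label, area, tally):
    flagged = area <= 0
    div = (lambda x: x / area) if not flagged else (lambda x: np.nan)
    return dict(
        sample_id=sample_id, phenotype=phenotype, level=level,
        compartment=compartment, inner_mm=inner, outer_mm=outer, band_label=label,
        analyzable_area_mm2=area, n_tls=tally["n"],
        count_density=div(tally["n"]),
        area_fraction=div(tally["tls_area"]),
        gc_bcl6pos_area_fraction=div(tally["gc_pos"]),
        gc_bcl6neg_area_fraction=div(tally["gc_neg"]),
        flagged=flagged,
    )


def _merge(tallies) -> dict:
    return {
        k: sum(t[k] for t in tallies) for k in ("n", "tls_area", "gc_pos", "gc_neg")
    }


def quantify_sample(scene: TissueScene, bands: BandTable) -> pd.DataFrame:
    """Tidy density table for one sample: phenotype x band (+ aggregates).

    Requires every retained TLS to be classified and band-assigned. Rows with
    ``level == "compartment"`` pool counts and areas over the bands of one
    compartment; the ``ALL`` phenotype pools the four TLS phenotypes
    (UNCLASSIFIED candidates are tabulated but never counted as TLS).
    """
    retained = [
        t for t in scene.tls_candidates
        if t.band_key is not None and t.band_key not in (BEYOND, DROPPED)
    ]
    for t in retained:
        if t.phenotype is None:
            raise ValueError(f"{scene.sample_id}: TLS {t.tls_id} not classified")

    tallies: dict[tuple, dict] = {}
    rows = []
    for band in bands.bands:
        for p in _PHENOS:
            members = [t for t in retained if t.band_key == band.key and t.phenotype is p]
            tally = _tally(scene.sample_id, members, band)
            tallies[(band.key, p)] = tally
            rows.append(_row(scene.sample_id, p.value, "band", band.compartment,
                             band.inner_mm, band.outer_mm, band.label,
                             band.analyzable_area, tally))
        rows.append(_row(scene.sample_id, ALL, "band", band.compartment,
                         band.inner_mm, band.outer_mm, band.label, band.analyzable_area,
                         _merge([tallies[(band.key, p)] for p in TLS_PHENOTYPES])))

    for compartment in ("INTRA", "EXTRA"):
        comp_bands = [b for b in bands.bands if b.compartment == compartment]
        pooled_area = sum(b.analyzable_area for b in comp_bands)
        label = f"{compartment}(all)"
        for p in _PHENOS:
            rows.append(_row(scene.sample_id, p.value, "compartment", compartment,
                             0.0, math.inf, label, pooled_area,
                             _merge([tallies[(b.key, p)] for b in comp_bands])))
        rows.append(_row(scene.sample_id, ALL, "compartment", compartment,
                         0.0, math.inf, label, pooled_area,
                         _merge([tallies[(b.key, p)]
                                 for b in comp_bands for p in TLS_PHENOTYPES])))

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def quantify_cohort(per_sample: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-sample density tables into one cohort table."""
    if not len(per_sample):
        raise ValueError("empty cohort")
    return pd.concat(list(per_sample), ignore_index=True)


# ---------------------------------------------------------------------------
# cohort summaries


def _group_of(metadata: Mapping[str, Mapping], sample_id: str, group_by: str) -> str:
    return str(metadata.get(sample_id, {}).get(group_by, "NA"))


def sample_tls_counts(records: pd.DataFrame) -> pd.Series:
    """Total retained TLS per sample (any phenotype)."""
    mask = (records["level"] == "compartment") & (records["phenotype"] == ALL)
    return records[mask].groupby("sample_id")["n_tls"].sum()


def prevalence(
    records: pd.DataFrame,
    metadata: Mapping[str, Mapping],
    group_by: str = "stage",
) -> pd.DataFrame:
    """Fraction of samples per group containing at least one TLS.

    A sample is TLS-positive iff it retains at least one classified TLS of
    any phenotype. Returns columns group, n_with_tls, n_total, percent (one
    decimal).
    """
    counts = sample_tls_counts(records)
    if counts.empty:
        raise ValueError("empty cohort")
    df = pd.DataFrame({
        "sample_id": counts.index,
        "positive": (counts > 0).to_numpy(),
    })
    df["group"] = [_group_of(metadata, s, group_by) for s in df["sample_id"]]
    out = (
        df.groupby("group")
        .agg(n_with_tls=("positive", "sum"), n_total=("positive", "size"))
        .reset_index()
    )
    out["percent"] = (100.0 * out["n_with_tls"] / out["n_total"]).round(1)
    return out


def phenotype_composition(
    records: pd.DataFrame,
    metadata: Mapping[str, Mapping],
    group_by: str = "stage",
) -> pd.DataFrame:
    """Per-group share of each TLS phenotype among all TLS of the group.

    Groups without any TLS get flagged rows (percent undefined).
    """
    mask = (records["level"] == "compartment") & records["phenotype"].isin(
        [p.value for p in TLS_PHENOTYPES]
    )
    df = records[mask].copy()
    df["group"] = [_group_of(metadata, s, group_by) for s in df["sample_id"]]
    rows = []
    for group, sub in df.groupby("group"):
        per_ph = sub.groupby("phenotype")["n_tls"].sum()
        total = int(per_ph.sum())
        for p in TLS_PHENOTYPES:
            n = int(per_ph.get(p.value, 0))
            rows.append(dict(
                group=group, phenotype=p.value, n_tls=n, n_total=total,
                percent=round(100.0 * n / total, 1) if total else np.nan,
                flagged=total == 0,
            ))
    return pd.DataFrame(rows)


def select_metric(
    records: pd.DataFrame,
    metric: str = "count_density",
    phenotype: str = ALL,
    compartment: str = "EXTRA",
    band: Optional[tuple[float, float]] = None,
) -> pd.Series:
    """One value per sample for a metric at a band or compartment level.

    ``band=None`` selects the compartment aggregate; otherwise ``(inner,
    outer)`` in mm selects one band. Flagged (zero-area) values are excluded.
    """
    if band is None:
        mask = records["level"] == "compartment"
    else:
        mask = (
            (records["level"] == "band")
            & (records["inner_mm"] == band[0])
            & (records["outer_mm"] == band[1])
        )
    mask &= (records["phenotype"] == phenotype) & (records["compartment"] == compartment)
    sub = records[mask & ~records["flagged"]]
    return sub.set_index("sample_id")[metric]
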