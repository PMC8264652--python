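"""Nonparametric cohort comparison workflow.

Two-group differences use the Wilcoxon rank sum (Mann-Whitney) test, exact
when both samples are small and tie-free, otherwise the normal approximation
with tie and continuity correction. Multi-group differences use
Kruskal-Wallis; prevalence contingency uses Fisher's exact test (two-sided,
point-probability rule); and every comparison plan forms one
Benjamini-Hochberg correction family. All tests are two-sided, and samples
(one value per sample) are the statistical unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .density import ALL, prevalence, select_metric

EXACT_MAX_N = 12  # exact Wilcoxon enumeration up to this combined sample size


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank sum test; returns (U statistic of x, p).

    Exact enumeration when ``len(x)+len(y) <= EXACT_MAX_N`` and there are no
    ties; otherwise the normal approximation with tie correction and
    continuity correction. Identical constant samples give p = 1 with a
    warning (no rank information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; H = 0, p = 1")
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided p is the sum of hypergeometric probabilities of all tables (at
    fixed margins) no more probable than the observed one. A zero margin
    leaves a degenerate table: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float], family_id: str = "") -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError(f"p-values outside [0,1] in family {family_id!r}")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# comparison plans


@dataclass
class Comparison:
    """One planned test over per-sample density values or prevalence counts."""

    comparison_id: str
    grouping: str  # metadata key
    groups: Optional[tuple[str, ...]] = None  # None = all levels (Kruskal if > 2)
    metric: str = "count_density"  # or "prevalence", "area_fraction", gc fractions
    phenotype: str = ALL
    compartment: str = "EXTRA"
    band: Optional[tuple[float, float]] = None  # None = compartment aggregate


@dataclass
class ComparisonPlan:
    plan_id: str
    comparisons: list[Comparison] = field(default_factory=list)


@dataclass
class ComparisonReport:
    comparison_id: str
    plan_id: str
    grouping: str
    test: str
    statistic: float
    p_raw: float
    p_fdr: float
    n_per_group: dict[str, int]
    effect: dict[str, float]  # per-group medians (or prevalence %)
    note: str = ""

    def to_row(self) -> dict:
        row = {
            "comparison_id": self.comparison_id, "plan_id": self.plan_id,
            "grouping": self.grouping, "test": self.test,
            "statistic": self.statistic, "p_raw": self.p_raw, "p_fdr": self.p_fdr,
            "n_per_group": ";".join(f"{k}={v}" for k, v in self.n_per_group.items()),
            "effect": ";".join(f"{k}={v:.4g}" for k, v in self.effect.items()),
            "note": self.note,
        }
        return row


SECFOL = "SECONDARY_FOLLICULAR"  # pooled secondary follicular pseudo-phenotype


def _pool_secondary(records: pd.DataFrame) -> pd.DataFrame:
    """Add pooled secondary-follicular rows (BCL6+ plus BCL6-) to a table."""
    sec = records[records["phenotype"].isin(
        ["SECONDARY_FOLLICULAR_BCL6NEG", "SECONDARY_FOLLICULAR_BCL6POS"]
    )]
    keys = ["sample_id", "level", "compartment", "inner_mm", "outer_mm",
            "band_label", "analyzable_area_mm2", "flagged"]
    pooled = (
        sec.groupby(keys, dropna=False)[
            ["n_tls", "count_density", "area_fraction",
             "gc_bcl6pos_area_fraction", "gc_bcl6neg_area_fraction"]
        ].sum(min_count=1).reset_index()
    )
    pooled["phenotype"] = SECFOL
    return pd.concat([records, pooled], ignore_index=True)


def builtin_plan(name: str) -> ComparisonPlan:
    """The built-in comparison plans mirroring the study's figure analyses.

    Band-level plans compare the first two bands of a compartment, whatever
    radii the density table was built with.
    """
    if name == "primary_vs_metastatic":
        groups = ("primary", "metastatic")
        return ComparisonPlan(name, [
            Comparison("prevalence", "stage_class", groups, metric="prevalence"),
            Comparison("extratumoral_density", "stage_class", groups,
                       metric="count_density", compartment="EXTRA"),
            Comparison("extratumoral_area", "stage_class", groups,
                       metric="area_fraction", compartment="EXTRA"),
            Comparison("intratumoral_density", "stage_class", groups,
                       metric="count_density", compartment="INTRA"),
            Comparison("intratumoral_area", "stage_class", groups,
                       metric="area_fraction", compartment="INTRA"),
        ])
    if name == "early_vs_late_metastases":
        groups = ("early_met", "late_met")
        return ComparisonPlan(name, [
            Comparison("prevalence", "stage", groups, metric="prevalence"),
            Comparison("extra_secfol_density", "stage", groups,
                       metric="count_density", phenotype=SECFOL),
            Comparison("extra_gc_bcl6neg_area", "stage", groups,
                       metric="gc_bcl6neg_area_fraction", phenotype=SECFOL),
        ])
    if name == "lymph_node_vs_skin":
        groups = ("lymph_node", "skin")
        return ComparisonPlan(name, [
            Comparison("extra_secfol_density", "site", groups,
                       metric="count_density", phenotype=SECFOL),
            Comparison("extra_gc_bcl6neg_area", "site", groups,
                       metric="gc_bcl6neg_area_fraction", phenotype=SECFOL),
        ])
    if name == "intratumoral_bands":
        # per-sample densities of the (0,1] vs (1,inf) intratumoral bands
        return ComparisonPlan(name, [
            Comparison("intra_band1_vs_beyond", "__band__", None,
                       metric="count_density", compartment="INTRA"),
        ])
    if name == "extratumoral_bands":
        return ComparisonPlan(name, [
            Comparison("extra_band1_vs_band2", "__band__", None,
                       metric="count_density", compartment="EXTRA"),
        ])
    raise KeyError(f"unknown plan {name!r}")


BUILTIN_PLANS = (
    "primary_vs_metastatic", "early_vs_late_metastases", "lymph_node_vs_skin",
    "intratumoral_bands", "extratumoral_bands",
)


def _stage_class(metadata: Mapping[str, Mapping]) -> dict[str, dict]:
    out = {}
    for s, rec in metadata.items():
        rec = dict(rec)
        stage = rec.get("stage")
        if stage is not None:
            rec["stage_class"] = "primary" if stage == "primary" else "metastatic"
        out[s] = rec
    return out


def run_comparisons(
    records: pd.DataFrame,
    metadata: Mapping[str, Mapping],
    plan: ComparisonPlan | str,
    alpha: float = 0.05,
) -> list[ComparisonReport]:
    """Run one comparison plan; BH correction applied within the plan family.

    ``metadata`` maps sample_id to fields like stage/site; a derived
    ``stage_class`` (primary vs metastatic) is available to plans. Group
    levels without samples skip their comparison with a note.
    """
    if isinstance(plan, str):
        plan = builtin_plan(plan)
    metadata = _stage_class(metadata)
    records = _pool_secondary(records)

    reports: list[ComparisonReport] = []
    for comp in plan.comparisons:
        rep = _run_one(records, metadata, comp, plan.plan_id)
        if rep is not None:
            reports.append(rep)
    adjusted = bh_adjust([r.p_raw for r in reports], family_id=plan.plan_id)
    for r, p in zip(reports, adjusted):
        r.p_fdr = float(p)
        r.note = (r.note + f" family={plan.plan_id} (m={len(reports)})").strip()
    return reports


def _run_one(records, metadata, comp: Comparison, plan_id: str) -> Optional[ComparisonReport]:
    if comp.grouping == "__band__":
        return _band_comparison(records, comp, plan_id)

    groups = comp.groups
    sample_group = {
        s: str(rec.get(comp.grouping)) for s, rec in metadata.items()
        if rec.get(comp.grouping) is not None
    }
    if groups is None:
        groups = tuple(sorted(set(sample_group.values())))

    if comp.metric == "prevalence":
        prev = prevalence(records, metadata, group_by=comp.grouping)
        prev = prev[prev["group"].isin(groups)]
        if len(prev) != 2 or (prev["n_total"] == 0).any():
            warnings.warn(f"{comp.comparison_id}: missing group, skipped")
            return None
        table = prev[["n_with_tls", "n_total"]].to_numpy()
        table = np.column_stack([table[:, 0], table[:, 1] - table[:, 0]])
        p = fisher_exact_2x2(table)
        return ComparisonReport(
            comp.comparison_id, plan_id, comp.grouping, "fisher_exact",
            statistic=float("nan"), p_raw=p, p_fdr=p,
            n_per_group=dict(zip(prev["group"], prev["n_total"])),
            effect=dict(zip(prev["group"], prev["percent"])),
        )

    values = select_metric(records, comp.metric, comp.phenotype, comp.compartment, comp.band)
    by_group: dict[str, np.ndarray] = {}
    for g in groups:
        samples = [s for s, gg in sample_group.items() if gg == g and s in values.index]
        by_group[g] = values.loc[samples].to_numpy(dtype=float)
    if any(len(v) == 0 for v in by_group.values()):
        warnings.warn(f"{comp.comparison_id}: empty group, skipped")
        return None
    if len(by_group) == 2:
        (ga, va), (gb, vb) = by_group.items()
        stat, p = wilcoxon_rank_sum(va, vb)
        test = "wilcoxon_rank_sum"
    else:
        stat, p = kruskal_wallis(list(by_group.values()))
        test = "kruskal_wallis"
    return ComparisonReport(
        comp.comparison_id, plan_id, comp.grouping, test,
        statistic=stat, p_raw=p, p_fdr=p,
        n_per_group={g: len(v) for g, v in by_group.items()},
        effect={g: float(np.median(v)) for g, v in by_group.items()},
    )


def _band_comparison(records, comp: Comparison, plan_id: str) -> Optional[ComparisonReport]:
    """Compare per-sample densities between the first two bands of a compartment."""
    sub = records[
        (records["level"] == "band")
        & (records["compartment"] == comp.compartment)
        & (records["phenotype"] == comp.phenotype)
        & ~records["flagged"]
    ]
    bands = sorted(
        {(i, o) for i, o in zip(sub["inner_mm"], sub["outer_mm"])},
        key=lambda b: b[0],
    )
    if len(bands) < 2:
        warnings.warn(f"{comp.comparison_id}: fewer than two bands, skipped")
        return None
    vals = []
    for b in bands[:2]:
        s = sub[(sub["inner_mm"] == b[0]) & (sub["outer_mm"] == b[1])]
        vals.append(s[comp.metric].to_numpy(dtype=float))
    stat, p = wilcoxon_rank_sum(vals[0], vals[1])
    labels = [f"({b[0]:g},{'inf' if np.isinf(b[1]) else format(b[1], 'g')}]" for b in bands[:2]]
    return ComparisonReport(
        comp.comparison_id, plan_id, "band", "wilcoxon_rank_sum",
        statistic=stat, p_raw=p, p_fdr=p,
        n_per_group={labels[0]: len(vals[0]), labels[1]: len(vals[1])},
        effect={labels[0]: float(np.median(vals[0])), labels[1]: float(np.median(vals[1]))},
    )


def reports_to_frame(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
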