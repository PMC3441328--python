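"""Cohort-level descriptive statistics and rank-based group comparisons.

Adoption times across a drug cohort are heavily skewed and the group
sizes uneven, so comparisons use the Kruskal-Wallis rank test (a
non-parametric one-way analysis of variance) rather than parametric
ANOVA.  The test is implemented directly from mid-ranks so that both the
tie-corrected and uncorrected statistics can be reported; the p-value
uses the chi-square approximation with k - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bass import EXTERNAL_DOMINANT, INTERNAL_DOMINANT

__all__ = [
    "GroupComparison",
    "median_iqr",
    "kruskal_wallis",
    "classify_table",
    "compare_groups_by_label",
    "summarize_table",
]


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis comparison of k groups."""

    h_statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]
    tie_corrected: bool = True
    h_uncorrected: float = float("nan")


def median_iqr(values) -> dict[str, float]:
    """Median and inter-quartile range of a sample.

    Quartiles use linear interpolation between order statistics (the
    numpy default).  Returns ``{"median", "q1", "q3"}``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr requires a non-empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def kruskal_wallis(groups, tie_correction: bool = True) -> GroupComparison:
    """Kruskal-Wallis H test across two or more groups.

    H = 12 / (N (N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2, computed on
    mid-ranks.  With ``tie_correction`` the statistic is divided by
    1 - sum(t^3 - t) / (N^3 - N) over tie groups of size t.  When every
    value is identical the correction degenerates; by convention H = 0,
    p = 1 (no evidence of any difference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    sizes = tuple(int(g.size) for g in groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    offset = 0
    for n_i in sizes:
        rbar = ranks[offset : offset + n_i].mean()
        h += n_i * (rbar - (n_total + 1) / 2.0) ** 2
        offset += n_i
    h *= 12.0 / (n_total * (n_total + 1))
    h_uncorrected = h
    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        divisor = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
        if divisor == 0.0:  # every value identical
            return GroupComparison(0.0, len(groups) - 1, 1.0, sizes, True, 0.0)
        h = h / divisor
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return GroupComparison(float(h), df, p, sizes, tie_correction, float(h_uncorrected))


def classify_table(table: pd.DataFrame, ratio_col: str = "pq_ratio") -> dict[str, pd.DataFrame]:
    """Partition a cohort table into external- vs internal-dominant drugs.

    External-dominant means p/q > 1; ties (p/q == 1) pool with internal.
    """
    if len(table) and table[ratio_col].isna().any():
        bad = table.loc[table[ratio_col].isna()].index.tolist()
        raise ValueError(f"rows with missing {ratio_col}: {bad}")
    mask = table[ratio_col] > 1
    return {"external": table[mask], "internal": table[~mask]}


def compare_groups_by_label(
    table: pd.DataFrame,
    label_field: str,
    value_field: str = "adoption_time_years",
    min_group_size: int = 4,
    tie_correction: bool = True,
) -> GroupComparison:
    """Kruskal-Wallis on ``value_field`` grouped by ``label_field``.

    Groups smaller than ``min_group_size`` are dropped before testing;
    fewer than two qualifying groups is an error.
    """
    groups = [
        g[value_field].to_numpy()
        for _, g in table.groupby(label_field, sort=True)
        if len(g) >= min_group_size
    ]
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 groups of size >= {min_group_size}; got {len(groups)}"
        )
    return kruskal_wallis(groups, tie_correction=tie_correction)


def summarize_table(table: pd.DataFrame) -> dict:
    """Headline cohort summary: medians/IQRs, class counts, two-group test.

    Expects columns ``adoption_time_years``, ``r2`` and ``pq_ratio`` (the
    shape written by the fitting pipeline and by the packaged reference
    table).  The external-vs-internal adoption-time comparison is reported
    with and without tie correction; it is skipped (with a reason) when
    either class is empty or the table has a single row.
    """
    out: dict = {"n_drugs": int(len(table))}
    out["adoption_time_years"] = median_iqr(table["adoption_time_years"])
    out["r2"] = median_iqr(table["r2"])
    parts = classify_table(table)
    n_ext, n_int = len(parts["external"]), len(parts["internal"])
    out["counts"] = {"external_dominant": n_ext, "internal_dominant": n_int}
    if n_ext == 0 or n_int == 0 or len(table) < 3:
        out["external_vs_internal"] = {
            "skipped": "requires both classes non-empty and >= 3 drugs"
        }
    else:
        groups = [
            parts["external"]["adoption_time_years"].to_numpy(),
            parts["internal"]["adoption_time_years"].to_numpy(),
        ]
        corrected = kruskal_wallis(groups, tie_correction=True)
        plain = kruskal_wallis(groups, tie_correction=False)
        out["external_vs_internal"] = {
            "h_statistic": corrected.h_statistic,
            "df": corrected.df,
            "p_value": corrected.p_value,
            "p_value_no_tie_correction": plain.p_value,
            "group_sizes": list(corrected.group_sizes),
        }
    return out
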