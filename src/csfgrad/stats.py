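"""Nonparametric cohort statistics.

Most laboratory and imaging variables in this setting are non-normal, so
group contrasts use rank-based tests and counts use Pearson chi-squared;
descriptives are medians with interquartile ranges.  Exact p-values are used
for small samples (rank-sum: total n ≤ 12 without ties; signed-rank: n ≤ 12
non-zero differences without tied magnitudes), otherwise the normal
approximation with tie and continuity corrections.  No multiple-testing
adjustment is applied by default; a Holm flag is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reiber

__all__ = [
    "rank_sum_test",
    "signed_rank_test",
    "chi_squared_test",
    "median_iqr",
    "summarize_cohort",
]


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U test for two independent samples.

    Returns (U of the first sample, p).  Exact enumeration when
    n_a + n_b ≤ 12 with no ties; otherwise normal approximation with midrank
    tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = a.size + b.size <= 12 and not _has_ties(np.concatenate([a, b]))
    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def signed_rank_test(pairs, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired (within-patient) values.

    ``pairs`` is a sequence of (x, y) pairs or a precomputed array of
    differences.  Zero differences are dropped; exact p for ≤ 12 non-zero
    differences without tied magnitudes, else normal approximation with
    correction.
    """
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    exact = diffs.size <= 12 and not _has_ties(np.abs(diffs))
    res = sps.wilcoxon(diffs, alternative=alternative,
                       method="exact" if exact else "approx", correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_squared_test(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a labelled count table.

    Continuity correction is off by default (identical rows then give
    p = 1.0 exactly); pass ``correction=True`` for Yates' correction.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D count table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("count table entries must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("count table has a zero marginal; test undefined")
    chi2, p, df, _ = sps.chi2_contingency(arr, correction=correction)
    return float(chi2), int(df), float(p)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation of order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------


def _fmt_median_iqr(values, scale=1.0, nd=2) -> str:
    med, q1, q3 = median_iqr(np.asarray(values) * scale)
    return f"{med:.{nd}f} ({q1:.{nd}f}-{q3:.{nd}f})"


def _fmt_n_pct(flags) -> str:
    flags = np.asarray(flags, dtype=bool)
    return f"{int(flags.sum())} ({100 * flags.mean():.1f}%)"


def summarize_cohort(
    profiles: pd.DataFrame,
    reiber_results: pd.DataFrame,
    group_labels: Mapping[str, str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Two-group laboratory report: median (IQR) or n (%) per variable.

    ``profiles`` is the raw laboratory table (columns of
    :data:`csfgrad.reiber.CSV_COLUMNS`, plus ``group`` unless
    ``group_labels`` supplies the split); ``reiber_results`` is the flattened
    classification from :func:`csfgrad.reiber.results_to_frame`.  Continuous
    rows use the rank-sum test, count rows the chi-squared test.  With
    ``holm=True`` a Holm-adjusted p column is appended.
    """
    profiles = profiles.copy()
    if group_labels is not None:
        profiles["group"] = profiles["patient_id"].map(dict(group_labels))
    if "group" not in profiles.columns:
        raise ValueError("no group column and no group_labels mapping supplied")
    if profiles["group"].isna().any():
        orphans = profiles.loc[profiles["group"].isna(), "patient_id"].tolist()
        raise ValueError(f"patients without a group label: {orphans}")
    merged = profiles.merge(reiber_results, on="patient_id", how="left", validate="1:1")
    missing = merged.loc[merged["q_alb_x1e3"].isna(), "patient_id"].tolist()
    if missing:
        raise ValueError(f"profiles without classification results: {missing}")
    groups = sorted(merged["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    ga = merged[merged["group"] == groups[0]]
    gb = merged[merged["group"] == groups[1]]

    continuous = [
        ("Age, years", "age", 1.0, 1),
        ("CSF albumin (mg/L)", "albumin_csf_mg_l", 1.0, 1),
        ("Serum albumin (g/L)", "albumin_serum_g_l", 1.0, 1),
        ("Quotient albumin CSF/serum (x1e3)", "q_alb_x1e3", 1.0, 2),
        ("Quotient IgG CSF/serum (x1e3)", "q_igg_x1e3", 1.0, 2),
        ("Percentage intrathecal IgG synthesis", "fraction_igg_pct", 1.0, 1),
        ("Absolute intrathecal IgG synthesis (mg/L)", "absolute_igg_mg_l", 1.0, 2),
        ("Quotient IgA CSF/serum (x1e3)", "q_iga_x1e3", 1.0, 2),
        ("Quotient IgM CSF/serum (x1e3)", "q_igm_x1e3", 1.0, 2),
        ("CSF leukocyte count (cells/uL)", "leukocytes_per_ul", 1.0, 0),
    ]
    binary = [
        ("Blood-CSF barrier dysfunction, n (%)", "barrier_dysfunction"),
        ("Intrathecal IgG synthesis, n (%)", "intrathecal_igg"),
        ("Intrathecal IgA synthesis, n (%)", "intrathecal_iga"),
        ("Intrathecal IgM synthesis, n (%)", "intrathecal_igm"),
        ("Oligoclonal bands positive, n (%)", "ocb_positive"),
    ]
    rows = []
    for label, col, scale, nd in continuous:
        if col not in merged.columns or merged[col].isna().all():
            continue
        va, vb = ga[col].dropna(), gb[col].dropna()
        stat, p = rank_sum_test(va, vb)
        rows.append({"variable": label,
                     groups[0]: _fmt_median_iqr(va, scale, nd),
                     groups[1]: _fmt_median_iqr(vb, scale, nd),
                     "test": "Mann-Whitney U", "statistic": stat, "p": p})
    for label, col in binary:
        if col not in merged.columns or merged[col].isna().all():
            continue
        fa = ga[col].dropna().astype(bool)
        fb = gb[col].dropna().astype(bool)
        tab = np.array([[fa.sum(), (~fa).sum()], [fb.sum(), (~fb).sum()]])
        if np.any(tab.sum(axis=0) == 0):
            continue  # degenerate: everyone (or no one) positive in both groups
        chi2, df, p = chi_squared_test(tab)
        rows.append({"variable": label,
                     groups[0]: _fmt_n_pct(fa), groups[1]: _fmt_n_pct(fb),
                     "test": "chi-squared", "statistic": chi2, "p": p})
    report = pd.DataFrame(rows)
    if holm and len(report):
        order = np.argsort(report["p"].to_numpy())
        m = len(report)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * report["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        report["p_holm"] = adj
    return report
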