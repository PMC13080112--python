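"""Feature screening: assumption-dispatched two-sample tests with BH-FDR.

Each feature is compared between groups with an independent two-sample
t-test when Shapiro-Wilk normality holds in both groups *and* Levene's test
finds homogeneous variances; otherwise the Mann-Whitney U test is used.
Raw p-values are adjusted with the Benjamini-Hochberg step-up procedure
within the feature family supplied by the caller (by default one paradigm's
26 features form a family).

The statistical unit defaults to the subject: the augmented segments of one
subject are averaged before testing, because segments of a subject are not
independent samples.  Segment-level testing is available via
``subject_level=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "dispatch_test", "bh_fdr", "screen_features", "ScreeningResult"]

META_COLUMNS = ("subject_id", "segment_id", "group", "paradigm", "moca")


@dataclass
class StatResult:
    feature: str
    test_used: str
    statistic: float
    p_raw: float
    p_fdr: float | None
    group_means_sd: dict[str, tuple[float, float]]
    flag: str = ""


def _normality_ok(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # degenerate sample: treat as violating normality
    return stats.shapiro(x).pvalue > alpha


def dispatch_test(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[str, float, float, str]:
    """Choose and run the two-sample test for one feature.

    Returns ``(test_used, statistic, p_raw, flag)``.  ``x`` and ``y`` are
    the two groups' values (NaN entries dropped).  Requires at least three
    valid observations per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 3 or len(y) < 3:
        return "none", np.nan, 1.0, "insufficient-data"
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return "none", np.nan, 1.0, "constant-in-both-groups"
    normal = _normality_ok(x, alpha) and _normality_ok(y, alpha)
    equal_var = stats.levene(x, y).pvalue > alpha if normal else False
    if normal and equal_var:
        res = stats.ttest_ind(x, y)
        return "t", float(res.statistic), float(res.pvalue), ""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return "mann-whitney", float(res.statistic), float(res.pvalue), ""


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreeningResult:
    retained: list[str]
    results: pd.DataFrame
    stat_results: list[StatResult]


def screen_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    subject_level: bool = True,
    feature_cols: list[str] | None = None,
    group_col: str = "group",
) -> ScreeningResult:
    """Screen a feature table for group differences (one FDR family).

    ``table`` holds one row per (subject, segment) with metadata columns
    plus feature columns.  Features with ``p_fdr < alpha`` are retained.  If
    nothing survives, ``retained`` is empty -- callers must handle that
    explicitly.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    if subject_level:
        data = table.groupby(["subject_id", group_col], as_index=False)[
            feature_cols
        ].mean()
    else:
        data = table
    g1 = data[data[group_col] == groups[0]]
    g2 = data[data[group_col] == groups[1]]
    results: list[StatResult] = []
    for feat in feature_cols:
        x = g1[feat].to_numpy(dtype=float)
        y = g2[feat].to_numpy(dtype=float)
        test_used, statistic, p_raw, flag = dispatch_test(x, y, alpha)
        means_sd = {
            groups[0]: (float(np.nanmean(x)) if np.any(~np.isnan(x)) else np.nan,
                        float(np.nanstd(x, ddof=1)) if np.sum(~np.isnan(x)) > 1 else np.nan),
            groups[1]: (float(np.nanmean(y)) if np.any(~np.isnan(y)) else np.nan,
                        float(np.nanstd(y, ddof=1)) if np.sum(~np.isnan(y)) > 1 else np.nan),
        }
        results.append(
            StatResult(feat, test_used, statistic, p_raw, None, means_sd, flag)
        )
    p_adj = bh_fdr([r.p_raw for r in results])
    for r, q in zip(results, p_adj):
        r.p_fdr = float(q)
    retained = [r.feature for r in results if r.p_fdr < alpha]
    frame = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            f"{groups[0]}_mean": [r.group_means_sd[groups[0]][0] for r in results],
            f"{groups[0]}_sd": [r.group_means_sd[groups[0]][1] for r in results],
            f"{groups[1]}_mean": [r.group_means_sd[groups[1]][0] for r in results],
            f"{groups[1]}_sd": [r.group_means_sd[groups[1]][1] for r in results],
            "test": [r.test_used for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "flag": [r.flag for r in results],
        }
    )
    return ScreeningResult(retained=retained, results=frame, stat_results=results)
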