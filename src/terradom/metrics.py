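"""Evaluation metrics: RMSE/NRMSE, SEM, and rank-based significance tests."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["rmse", "nrmse", "sem", "wilcoxon_compare", "jaccard"]


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def nrmse(rmse_value: float, target_values) -> float:
    """RMSE as a percentage of the target's full range (max - min)."""
    t = np.asarray(target_values, dtype=float)
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("constant target: NRMSE undefined")
    return 100.0 * rmse_value / span


def sem(values) -> float:
    """Standard error of the mean over repeated model trainings (sample sd)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM requires at least two values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def wilcoxon_compare(a, b, paired: bool) -> float:
    """Two-sided rank test with continuity correction; returns the p-value.

    Paired vectors use the Wilcoxon signed-rank test (zero differences
    dropped, the standard signed-rank convention); unpaired vectors use the
    rank-sum test.  Both use the continuity-corrected normal approximation
    with average ranks for ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires equal-length vectors")
        diffs = a - b
        if np.all(diffs == 0):
            raise ValueError("all paired differences are zero")
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=True, method="approx",
            alternative="two-sided",
        )
    else:
        res = stats.mannwhitneyu(
            a, b, use_continuity=True, alternative="two-sided", method="asymptotic"
        )
    return float(res.pvalue)


def jaccard(a, b) -> float:
    """|A intersect B| / |A union B|; two empty sets count as identical (1)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)
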