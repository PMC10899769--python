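"""Rank-based statistical annotations used throughout the pipeline.

Thin, explicit wrappers around scipy/statsmodels: one-sample Wilcoxon
signed-rank against a reference median (with an enrichment/depletion
direction), Kruskal-Wallis, Mann-Whitney U, pairwise Spearman matrices with
a significance mask, and Benjamini-Hochberg adjustment.  Signed-rank and U
tests use the exact null distribution for small samples (n < 26, no ties)
and the tie/continuity-corrected normal approximation otherwise, following
scipy's 'auto' policy.  Values exactly tying the reference are dropped
before the signed-rank test (Wilcoxon's original treatment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_vs_reference",
    "kruskal_wallis",
    "mann_whitney",
    "spearman_matrix",
    "benjamini_hochberg",
]


def wilcoxon_vs_reference(values, reference: float):
    """Two-sided one-sample signed-rank test of values against a reference.

    Returns (p, direction) where direction is 'enriched' when the median
    difference is positive, 'depleted' when negative, 'none' otherwise.
    All-tied input gives (1.0, 'none').
    """
    diffs = np.asarray(values, dtype=float) - reference
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0, "none"
    res = sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided", method="auto")
    med = float(np.median(diffs))
    direction = "enriched" if med > 0 else "depleted" if med < 0 else "none"
    return float(res.pvalue), direction


def kruskal_wallis(groups: dict) -> float:
    """Kruskal-Wallis omnibus p-value over named groups (tie-corrected H)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        return 1.0
    return float(sps.kruskal(*samples).pvalue)


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def spearman_matrix(table: pd.DataFrame, alpha: float = 0.01):
    """Pairwise Spearman rho (midranks) with a p < alpha significance mask.

    Constant columns give NaN rho and a False mask against every other
    column.  The diagonal is rho 1, masked True.
    """
    if len(table) < 3:
        raise ValueError("spearman_matrix needs at least 3 rows")
    cols = list(table.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    mask = pd.DataFrame(np.eye(k, dtype=bool), index=cols, columns=cols)
    arr = table.to_numpy(dtype=float)
    constant = np.array([np.all(arr[:, j] == arr[0, j]) for j in range(k)])
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(arr[:, i], arr[:, j])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            sig = bool(p < alpha) if not np.isnan(p) else False
            mask.iloc[i, j] = mask.iloc[j, i] = sig
    return rho, mask


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving, monotone."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
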