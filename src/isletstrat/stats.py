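"""Shared statistical primitives: Mann-Whitney U and Benjamini-Hochberg.

Single source of truth for every group comparison in the package
(TF-group gene tests, single-cell differential expression, and the
electrophysiology comparisons all route through these functions).

Conventions
-----------
* Two-sided Mann-Whitney U. The exact null distribution is used when both
  samples have at most `exact_max` (default 8) observations and carry no
  ties; otherwise the normal approximation with tie correction (and
  continuity correction) is used.
* If every value in the pooled sample is identical the test is degenerate
  and p = 1 with U = n*m/2.
* BH adjustment via the standard step-up procedure; adjusted p-values are
  monotone and never smaller than the raw p.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_DEFAULT = 8


def mann_whitney_u(x, y, exact_max: int = EXACT_MAX_DEFAULT) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of x vs y.

    Returns (U, p) where U is the statistic of the first sample
    (number of (x, y) pairs with x > y, ties counting 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= exact_max and y.size <= exact_max:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mann_whitney_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided Mann-Whitney U (normal approximation).

    A and B are dense arrays (cells x genes); each column is one test.
    Columns where the pooled values are constant get p = 1.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    res = sps.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    pooled_ptp = np.ptp(np.concatenate([A, B], axis=0), axis=0)
    degenerate = pooled_ptp == 0
    u[degenerate] = A.shape[0] * B.shape[0] / 2.0
    p[degenerate] = 1.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    return u, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(p: float, levels=(0.05, 0.01)) -> str:
    """'*' for p < 0.05, '**' for p < 0.01, '' otherwise (NaN-safe)."""
    if p is None or not np.isfinite(p):
        return ""
    if p < levels[1]:
        return "**"
    if p < levels[0]:
        return "*"
    return ""
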