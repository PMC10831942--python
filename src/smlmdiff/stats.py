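"""Endpoint survival and group-comparison statistics.

Cell survival after membrane wounding is compared between genotypes with the
two-sided Fisher exact test on a 2x2 alive/dead table (minimum-likelihood
two-sided convention: sum over all tables with the margins fixed whose
hypergeometric probability does not exceed that of the observed table).
Multiple group comparisons use two-sided Welch t-tests with Holm step-down
adjustment of the p values.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_exact_2x2", "holm_adjust", "welch_t", "pairwise_welch"]


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        ti = np.asarray(table, dtype=float)
        if not np.all(ti == np.round(ti)):
            raise ValueError("counts must be integers")
        t = ti.astype(np.int64)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p value for a 2x2 contingency table."""
    t = _validate_table(table)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch (unequal-variance) t-test p value for two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise ValueError("zero variance in both groups with unequal means")
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def pairwise_welch(
    groups: Sequence[np.ndarray], adjust: bool = True
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Welch t-tests for all group pairs, optionally Holm-adjusted.

    Returns the list of compared (i, j) index pairs and the (adjusted)
    p values in the same order.
    """
    pairs = list(combinations(range(len(groups)), 2))
    p = np.array([welch_t(groups[i], groups[j]) for i, j in pairs])
    return pairs, (holm_adjust(p) if adjust and len(p) else p)
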