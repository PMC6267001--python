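"""Elementary association tests and multiple-testing adjustment.

Spearman rank correlation (cross-sectional), Wilcoxon signed-rank (paired
longitudinal), Wilcoxon rank-sum / Mann-Whitney (unpaired group contrast),
and Benjamini-Hochberg step-up FDR adjustment.  The signed-rank and rank-sum
tests are thin policy wrappers over scipy; the Spearman p-value adds an exact
small-sample permutation mode (n <= 9, untied) that scipy does not expose,
with the tie-aware t approximation otherwise.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ConstantInputError

#: Largest n for which the exact Spearman permutation null is enumerated.
EXACT_SPEARMAN_MAX_N = 9
#: Largest number of nonzero pairs for which signed-rank uses the exact null.
EXACT_WILCOXON_MAX_N = 25


@lru_cache(maxsize=None)
def _spearman_null_abs(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank pairings (untied case)."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.sort(np.abs(rho))


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho and two-sided p between two equal-length vectors.

    Average ranks are used for rho.  For n <= 9 with no ties in either
    vector, the p-value is exact, from full enumeration of the permutation
    null; otherwise the usual t-distribution approximation is used.
    Constant input is undefined and raises :class:`ConstantInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D vectors, got {x.shape} vs {y.shape}")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman correlation undefined for a constant vector")

    untied = len(np.unique(x)) == n and len(np.unique(y)) == n
    if untied and n <= EXACT_SPEARMAN_MAX_N:
        rx = scipy.stats.rankdata(x) - 1
        ry = scipy.stats.rankdata(y) - 1
        d2 = ((rx - ry) ** 2).sum()
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        null = _spearman_null_abs(n)
        # two-sided: mass of |rho_perm| >= |rho_obs| (with float-safety slack)
        count = len(null) - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return float(rho), float(count / len(null))
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(before, after) -> tuple[float, float]:
    """Paired two-sided signed-rank test of ``after`` vs ``before``.

    Zero differences are dropped (classic Wilcoxon treatment).  All-zero
    differences are a degenerate, not an error: returns (0.0, 1.0).  The
    exact null is used for <= 25 nonzero, untied |differences|; otherwise the
    tie-corrected normal approximation.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1-D vectors")
    d = after - before
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    absd = np.abs(d)
    exact = len(d) <= EXACT_WILCOXON_MAX_N and len(np.unique(absd)) == len(d)
    res = scipy.stats.wilcoxon(d, method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two independent samples.

    Exact for small untied samples (scipy's 'auto' policy), tie-corrected
    normal approximation otherwise.  Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be a 1-D vector")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
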