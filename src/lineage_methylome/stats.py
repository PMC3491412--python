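"""Shared statistical primitives.

Thin, convention-fixing wrappers around scipy/statsmodels: every hypothesis
test used by the analysis modules (rank-sum, Fisher 2x2, Benjamini-Hochberg)
funnels through here so that tie handling, exactness switching and degenerate
inputs are decided once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "rank_sum_test",
    "fisher_2x2",
    "bh_adjust",
]

# exact Mann-Whitney enumeration is cheap up to this combined sample size
_EXACT_N_MAX = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or 2x2 test.

    ``statistic`` is the test statistic (U for rank-sum, odds ratio for
    Fisher); ``pvalue`` the p-value for the requested alternative;
    ``testable`` is False when the inputs made the test undefined (an empty
    side, a constant vector), in which case ``pvalue`` is NaN.
    """

    statistic: float
    pvalue: float
    testable: bool = True
    note: str = ""

    @classmethod
    def not_testable(cls, note: str) -> "TestResult":
        return cls(statistic=float("nan"), pvalue=float("nan"), testable=False, note=note)


def rank_sum_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of ``x`` against ``y``.

    Uses the exact null distribution (inclusive convention,
    p = P(U >= u_obs)) when the combined sample size is <= 20 and there are
    no ties; otherwise the normal approximation with continuity and tie
    correction. All values tied across both groups yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return TestResult.not_testable("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # no rank information at all
        return TestResult(statistic=x.size * y.size / 2.0, pvalue=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= _EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(statistic=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)))


def fisher_2x2(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    Returns the conditional odds ratio estimate as the statistic.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    res = sps.fisher_exact(table, alternative=alternative)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    return multipletests(p, method="fdr_bh")[1]
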