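"""Hypothesis tests and correlations used throughout the pipeline.

Thin, contract-enforcing wrappers over :mod:`scipy.stats`.  The rank-sum
normal approximation is tie-corrected and continuity-corrected (scipy's
asymptotic Mann-Whitney), which is the variant that reproduces group tests
on small genomic-average panels; the exact method enumerates the rank-sum
distribution and refuses tied data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _ss

Sides = Literal["two", "greater", "less"]
_ALTERNATIVE = {"two": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_ranksum(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "exact", "normal_approx"] = "auto",
    sides: Sides = "two",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    ``normal_approx`` uses the U statistic with tie-corrected variance
    n1*n2/12 * [(N+1) - sum(t^3-t)/(N(N-1))] and a 0.5 continuity
    correction.  ``exact`` enumerates the null distribution and raises on
    ties.  ``auto`` picks exact for tie-free samples with n1+n2 <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = _has_ties(x, y)
    if method == "auto":
        method = "exact" if (not ties and x.size + y.size <= 20) else "normal_approx"
    if method == "exact":
        if ties:
            raise ValueError("exact rank-sum method is invalid in the presence of ties")
        res = _ss.mannwhitneyu(x, y, alternative=_ALTERNATIVE[sides], method="exact")
    elif method == "normal_approx":
        res = _ss.mannwhitneyu(
            x, y, alternative=_ALTERNATIVE[sides], method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(float(res.statistic), float(res.pvalue), method, x.size, y.size)


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation; p from t = R*sqrt((n-2)/(1-R^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    r, p = _ss.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", x.size, x.size)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Rank correlation on mid-ranks; p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    rho, p = _ss.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman", x.size, x.size)
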