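"""Group-comparison utilities used throughout the pipeline.

All group results are reported as median (IQR) with nonparametric
(Mann-Whitney U) testing and Bonferroni adjustment for multiple
comparisons, matching common practice for small animal cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "TestResult", "mann_whitney_u", "bonferroni_adjust", "summarize"]

#: exact enumeration is used when n1*n2 is at or below this bound and there are no ties
EXACT_LIMIT = 400


@dataclass(frozen=True)
class GroupSummary:
    """Median and quartiles (linear-interpolation rule) of one group."""

    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class TestResult:
    """Two-sided Mann-Whitney U result; U is reported for the first sample."""

    statistic: float
    p_raw: float
    p_adjusted: float
    n1: int
    n2: int
    method: str = "exact"


def mann_whitney_u(a: Sequence[float], b: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used when ``n1*n2 <= 400`` and there are
    no ties; otherwise a tie-corrected normal approximation (with continuity
    correction) is applied.  ``mode`` may force ``"exact"`` or
    ``"normal-approx"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u: both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        exact = (a.size * b.size <= EXACT_LIMIT) and not has_ties
    elif mode == "exact":
        exact = True
    elif mode in ("normal-approx", "asymptotic"):
        exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    p = float(min(1.0, res.pvalue))
    return TestResult(
        statistic=float(res.statistic),
        p_raw=p,
        p_adjusted=p,
        n1=int(a.size),
        n2=int(b.size),
        method="exact" if exact else "normal-approx",
    )


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: each p -> min(1, p*m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return [float(min(1.0, v * m)) for v in p]


def summarize(sample: Sequence[float]) -> GroupSummary:
    """Median / Q1 / Q3 by the linear-interpolation quantile rule."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("summarize: need at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(n=int(x.size), median=float(med), q1=float(q1), q3=float(q3))
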