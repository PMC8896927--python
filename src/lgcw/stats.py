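"""Clinical efficacy statistics.

Two-arm treatment studies of this kind summarize each arm by counts of
markedly-effective / effective / ineffective outcomes.  The total effective
rate collapses the first two categories:

    total effective rate (%) = 100 * (markedly_effective + effective) / total

Group comparisons follow the usual toolkit: Pearson chi-square for
categorical outcomes (collapsed 2x2 table, df=1, no continuity correction
by default), Welch's t-test from mean/SD/n summaries for normal variables,
and the Mann-Whitney rank-sum test (normal approximation with tie
correction) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTableError, InvalidParameterError, UndefinedStatisticError

__all__ = [
    "EfficacyCounts",
    "GroupSummary",
    "total_effective_rate",
    "category_percentages",
    "chi_square_2x2",
    "welch_t_from_summary",
    "rank_sum",
]


@dataclass(frozen=True)
class EfficacyCounts:
    """Outcome counts for one study arm."""

    markedly_effective: int
    effective: int
    ineffective: int

    def __post_init__(self):
        if min(self.markedly_effective, self.effective, self.ineffective) < 0:
            raise InvalidParameterError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.markedly_effective + self.effective + self.ineffective

    def collapsed(self) -> tuple[int, int]:
        """(effective-or-better, ineffective) — the 2x2 test's row."""
        return (self.markedly_effective + self.effective, self.ineffective)


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidParameterError("sd must be >= 0")
        if self.n < 2:
            raise InvalidParameterError("n must be >= 2")


def total_effective_rate(counts: EfficacyCounts) -> float:
    """Percentage of cases at least effective, rounded to 2 decimals."""
    if counts.total == 0:
        raise InvalidParameterError("total count must be positive")
    return round(100.0 * (counts.markedly_effective + counts.effective) / counts.total, 2)


def category_percentages(counts: EfficacyCounts) -> tuple[float, float, float]:
    """Per-category percentages (markedly effective, effective, ineffective)."""
    if counts.total == 0:
        raise InvalidParameterError("total count must be positive")
    return tuple(
        round(100.0 * c / counts.total, 2)
        for c in (counts.markedly_effective, counts.effective, counts.ineffective)
    )


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (df=1, upper-tail p).

    Continuity (Yates) correction is off by default; pass
    ``correction=True`` to enable it.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise InvalidParameterError("table must be 2x2")
    if (table < 0).any():
        raise InvalidParameterError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("a zero margin makes the chi-square test degenerate")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch's two-sample t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise UndefinedStatisticError("t undefined: zero variance and equal means")
        return float("inf"), float(a.n + b.n - 2), 0.0
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def rank_sum(a, b) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction.

    Returns (U for the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
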