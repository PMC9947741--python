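"""Phenotypic summary statistics: 2x2 chi-squared, pooled t-test, Pearson CI.

Thin, explicit wrappers over scipy.stats matching the conventions used for
the cohort-level lesion comparisons: Pearson chi-squared without continuity
correction, pooled-variance two-sample t from summary statistics, and a
Fisher-z confidence interval for a correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TwoByTwoTable", "chi2_2x2", "t_test_pooled", "pearson_ci"]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts for a 2x2 contingency table, rows = groups, cols = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        arr = self.as_array()
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("2x2 table has a zero marginal; statistic undefined")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi2_2x2(table: TwoByTwoTable) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table.

    Returns (statistic, df, p); df is always 1.
    """
    if not isinstance(table, TwoByTwoTable):
        table = TwoByTwoTable(*np.asarray(table, dtype=int).ravel())
    chi2, p, df, _ = sps.chi2_contingency(table.as_array(), correction=False)
    return float(chi2), int(df), float(p)


def t_test_pooled(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test from summary statistics.

    Returns (t, df, two-tailed p) with df = n1 + n2 - 2. Raises if the
    pooled variance is zero while the means differ (infinite statistic).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0 and mean1 != mean2:
        raise ZeroDivisionError("zero pooled variance with unequal means")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), int(n1 + n2 - 2), float(res.pvalue)


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation.

    tanh(atanh(r) +- z * 1/sqrt(n-3)) at the requested two-sided level.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if n <= 3:
        raise ValueError("Fisher-z interval requires n > 3")
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return float(np.tanh(zr - half)), float(np.tanh(zr + half))
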