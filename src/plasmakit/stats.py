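"""Cohort-level statistics used in the reports.

Thin, validated wrappers around scipy: two-sided Fisher's exact test
(probability-mass definition: the p-value sums hypergeometric
probabilities of all tables with the same margins that are no more likely
than the observed one), Spearman rank correlation with midranks, and the
one-sided Wilcoxon rank-sum test (exact for small tie-free samples,
normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "spearman_rho",
    "ranksum_one_sided",
]


@dataclass
class ContingencyTable2x2:
    """2x2 table of counts; rows are cohorts, columns event / non-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"count {name} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Accepts a :class:`ContingencyTable2x2` or anything convertible to a
    2x2 integer array.
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        table = ContingencyTable2x2(*arr.ravel().tolist())
    return float(_sps.fisher_exact(table.as_array())[1])


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midrank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for constant input")
    return float(_sps.spearmanr(x, y).statistic)


def ranksum_one_sided(a, b) -> float:
    """One-sided Wilcoxon rank-sum p-value for the alternative a < b.

    Exact for small samples without ties; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(
        _sps.mannwhitneyu(a, b, alternative="less", method="auto").pvalue
    )
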