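"""Contingency-table association tests and false-discovery-rate adjustment.

Conventions follow the R analysis stack these statistics are usually
computed with: 2x2 chi-square tests apply the Yates continuity correction,
Fisher's two-sided p sums hypergeometric probabilities no larger than the
observed table's, and multiple testing is corrected with the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TestResult",
    "build_contingency",
    "chi_square",
    "fisher_exact_2x2",
    "two_sample_t",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.sum() < 1:
            raise ValueError("table must contain at least one observation")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValueError("label lengths must match table shape")

    def expected(self) -> np.ndarray:
        """Expected counts under independence of rows and columns."""
        c = self.counts
        return np.outer(c.sum(axis=1), c.sum(axis=0)) / c.sum()


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[int] = None
    estimate: Optional[float] = None


def build_contingency(labels_a: Sequence, labels_b: Sequence) -> ContingencyTable:
    """Cross-tabulate two per-sample label vectors.

    Samples with a missing label (``None`` or NaN) in either vector are
    dropped pairwise; levels are ordered by first appearance.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")

    def _missing(x) -> bool:
        return x is None or (isinstance(x, float) and np.isnan(x))

    pairs = [(a, b) for a, b in zip(labels_a, labels_b) if not (_missing(a) or _missing(b))]
    rows = list(dict.fromkeys(a for a, _ in pairs))
    cols = list(dict.fromkeys(b for _, b in pairs))
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("need at least two levels in each vector after dropping missing")
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for a, b in pairs:
        counts[rows.index(a), cols.index(b)] += 1
    return ContingencyTable(counts, tuple(map(str, rows)), tuple(map(str, cols)))


def chi_square(table: ContingencyTable, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test; optional Yates correction (2x2 only)."""
    if continuity_correction and table.counts.shape != (2, 2):
        raise ValueError("continuity correction is defined only for 2x2 tables")
    if (table.expected() == 0).any():
        raise ValueError("chi-square undefined: an expected count is zero")
    stat, p, df, _ = stats.chi2_contingency(table.counts, correction=continuity_correction)
    return TestResult(statistic=float(stat), p_value=float(p), df=int(df))


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test with the sample odds ratio (ad/bc)."""
    c = table.counts
    if c.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("Fisher's exact test undefined for a zero margin")
    odds, p = stats.fisher_exact(c, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), estimate=float(odds))


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Welch two-sided t-test on group means."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return TestResult(statistic=0.0, p_value=1.0)
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(stat), p_value=float(p))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()
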