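"""Contingency-table statistics for selection-agreement analyses.

Pearson chi-squared tests of independence (no continuity correction),
pairwise post-hoc comparisons of table rows with Benjamini-Hochberg
adjustment, and Cramér's V effect sizes — the toolkit used to compare
how often programs/criteria recover the generating model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError


@dataclass
class ContingencyTable:
    """Labeled rows x columns of non-negative integer counts."""

    row_labels: list[str]
    counts: np.ndarray
    col_labels: tuple[str, ...] = ("Yes", "No")

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidInputError("counts must be a 2-D matrix")
        if self.counts.shape[0] != len(self.row_labels):
            raise InvalidInputError("one label per row required")
        if self.counts.shape[1] != len(self.col_labels):
            raise InvalidInputError("one label per column required")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def subtable(self, rows) -> "ContingencyTable":
        idx = [self.row_labels.index(r) for r in rows]
        return ContingencyTable(
            [self.row_labels[i] for i in idx], self.counts[idx], self.col_labels
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=list(self.col_labels)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(list(df.index), df.to_numpy(), tuple(df.columns))


def chi2_independence(table: ContingencyTable):
    """Pearson chi-squared test of independence, df = (r-1)(c-1).

    No continuity correction is applied (also for 2x2 tables).
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InvalidInputError("need at least a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        zero_rows = [
            table.row_labels[i] for i in np.flatnonzero(counts.sum(axis=1) == 0)
        ]
        raise InvalidInputError(
            f"zero margin in contingency table (empty rows: {zero_rows}); "
            "expected counts are undefined"
        )
    chi2, p, df, _ = chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def cramers_v(table: ContingencyTable) -> float:
    """Cramér's V = sqrt(chi2 / (N (min(r,c) - 1))), no bias correction."""
    chi2, _, _ = chi2_independence(table)
    r, c = table.counts.shape
    return float(np.sqrt(chi2 / (table.n * (min(r, c) - 1))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairwiseResult:
    """One post-hoc 2x2 comparison of two table rows."""

    pair: str
    chi2: float
    p_raw: float
    p_adj: float
    cramer_v: float


def pairwise_nominal_independence(table: ContingencyTable) -> list[PairwiseResult]:
    """Post-hoc pairwise chi-squared tests between all row pairs.

    Each unordered row pair forms a 2x2 sub-table tested without
    continuity correction; raw p-values are BH-adjusted across the
    pairs.  Pairs with a degenerate margin are reported with NaN
    statistics and excluded from the adjustment (with a warning).
    """
    labels = table.row_labels
    if len(labels) < 2:
        raise InvalidInputError("need at least two rows for pairwise tests")
    results: list[PairwiseResult] = []
    testable: list[int] = []
    for idx, (a, b) in enumerate(combinations(labels, 2)):
        sub = table.subtable([a, b])
        try:
            chi2, _, p = chi2_independence(sub)
            v = float(np.sqrt(chi2 / sub.n))
        except InvalidInputError:
            warnings.warn(
                f"pair {a}:{b} has a zero margin; excluded from adjustment",
                stacklevel=2,
            )
            results.append(PairwiseResult(f"{a}: {b}", np.nan, np.nan, np.nan, np.nan))
            continue
        results.append(PairwiseResult(f"{a}: {b}", chi2, p, np.nan, v))
        testable.append(idx)
    if testable:
        adj = bh_adjust([results[i].p_raw for i in testable])
        for i, pa in zip(testable, adj):
            results[i].p_adj = float(pa)
    return results


def pairwise_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    """Pairwise results in the conventional report layout."""
    return pd.DataFrame(
        {
            "Comparison": [r.pair for r in results],
            "p.Chisq": [r.p_raw for r in results],
            "p.adj.Chisq": [r.p_adj for r in results],
            "Cramer.V": [r.cramer_v for r in results],
        }
    )
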