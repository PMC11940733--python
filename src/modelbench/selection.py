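"""Information criteria and best-model selection over a set of fits.

All three criteria score a fit as ``-2 lnL`` plus a parameter penalty:
AIC adds ``2k``; AICc adds the small-sample correction
``2k(k+1)/(n-k-1)`` on top of AIC; BIC adds ``k ln(n)``.  The sample
size ``n`` is the alignment length in sites, the convention of the
common model-selection programs.  Smaller scores are better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import InvalidInputError
from .model_space import complexity_rank

CRITERIA = ("AIC", "AICc", "BIC")


def aic(lnl: float, k: int) -> float:
    """Akaike information criterion: -2 lnL + 2k."""
    if not math.isfinite(lnl):
        raise InvalidInputError(f"lnL must be finite, got {lnl}")
    if k < 0:
        raise InvalidInputError(f"k must be >= 0, got {k}")
    return -2.0 * lnl + 2.0 * k


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise InvalidInputError(
            f"AICc undefined for n={n}, k={k} (needs n > k + 1)"
        )
    return aic(lnl, k) + 2.0 * k * (k + 1) / (n - k - 1)


def bic(lnl: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2 lnL + k ln(n)."""
    if not math.isfinite(lnl):
        raise InvalidInputError(f"lnL must be finite, got {lnl}")
    if k < 0:
        raise InvalidInputError(f"k must be >= 0, got {k}")
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    return -2.0 * lnl + k * math.log(n)


_SCORERS = {"AIC": lambda l, k, n: aic(l, k), "AICc": aicc, "BIC": bic}


@dataclass
class SelectionRecord:
    """Ranked criterion scores for one alignment.

    ``table`` is sorted ascending by score with columns model, lnl, k,
    score and delta (score minus the best score).
    """

    alignment_id: str | None
    criterion: str
    table: pd.DataFrame
    best: str

    @property
    def best_k(self) -> int:
        return int(self.table.iloc[0]["k"])


def select_best(
    fits, criterion: str, n: int | None = None
) -> SelectionRecord:
    """Pick the argmin-score model among ``fits`` under ``criterion``.

    Ties are broken deterministically: smaller k first, then lower
    complexity rank.
    """
    fits = list(fits)
    if not fits:
        raise InvalidInputError("select_best needs at least one fit")
    if criterion not in _SCORERS:
        raise InvalidInputError(f"unknown criterion {criterion!r}")
    ids = {f.alignment_id for f in fits}
    if len(ids) > 1:
        raise InvalidInputError(f"fits come from different alignments: {ids}")
    sizes = {f.n_sites for f in fits}
    if n is None:
        if len(sizes) != 1:
            raise InvalidInputError("fits disagree on n_sites; pass n explicitly")
        n = sizes.pop()
    scorer = _SCORERS[criterion]
    rows = [
        {
            "model": f.model.name,
            "lnl": f.lnl,
            "k": f.k,
            "score": scorer(f.lnl, f.k, n),
            "rank": complexity_rank(f.model),
            "converged": f.converged,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(
        ["score", "k", "rank"], kind="stable", ignore_index=True
    )
    table["delta"] = table["score"] - table["score"].iloc[0]
    table = table.drop(columns="rank")
    return SelectionRecord(
        alignment_id=next(iter(ids)),
        criterion=criterion,
        table=table,
        best=str(table.iloc[0]["model"]),
    )


def selection_summary(record: SelectionRecord) -> str:
    """One-line human-readable summary of a selection."""
    top = record.table.iloc[0]
    return (
        f"{record.criterion}: best={record.best} "
        f"(lnL={top['lnl']:.4f}, k={int(top['k'])}, score={top['score']:.4f})"
    )
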