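"""Scoring recovery of the generating model and cross-criterion agreement.

Two selected models are "similar" when they differ by at most a
threshold (default 4) number of positions in the complexity-ordered
registry; exact recovery means the selected name equals the generating
name.  Outcomes aggregate into labeled yes/no contingency tables that
feed the chi-squared layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .model_space import SubstitutionModel, complexity_rank, get_model
from .stats import ContingencyTable


def similar_models(
    a: SubstitutionModel | str,
    b: SubstitutionModel | str,
    threshold: int = 4,
    metric: str = "rank",
) -> bool:
    """Whether two registry models differ by at most ``threshold``.

    ``metric="rank"`` (default) measures positions in the
    complexity-ordered registry; ``metric="params"`` measures free
    model-parameter counts instead.  Symmetric in its arguments.
    """
    if metric == "rank":
        da = complexity_rank(a)
        db = complexity_rank(b)
    elif metric == "params":
        da = (get_model(a) if isinstance(a, str) else a).k_model
        db = (get_model(b) if isinstance(b, str) else b).k_model
    else:
        raise InvalidInputError(f"unknown similarity metric {metric!r}")
    return abs(da - db) <= threshold


@dataclass
class RecoveryOutcome:
    """Did one (dataset, criterion) selection recover the generating model?"""

    dataset: str
    criterion: str
    selected: str
    truth: str
    correct: bool
    similar: bool

    @classmethod
    def from_selection(
        cls, dataset: str, criterion: str, selected: str, truth: str, threshold: int = 4
    ) -> "RecoveryOutcome":
        correct = selected == truth
        return cls(
            dataset=dataset,
            criterion=criterion,
            selected=selected,
            truth=truth,
            correct=correct,
            similar=correct or similar_models(selected, truth, threshold),
        )


def recovery_contingency(
    outcomes, group_by: str = "criterion", field: str = "correct"
) -> ContingencyTable:
    """Aggregate outcomes into a labels x (Yes, No) table.

    ``group_by`` may be ``"criterion"`` or any outcome attribute (e.g. a
    program label stored in ``dataset``); ``field`` selects which binary
    classification is counted (``correct`` or ``similar``).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise InvalidInputError("no outcomes to aggregate")
    labels: list[str] = []
    counts: dict[str, list[int]] = {}
    for o in outcomes:
        label = getattr(o, group_by)
        flag = bool(getattr(o, field))
        if label not in counts:
            counts[label] = [0, 0]
            labels.append(label)
        counts[label][0 if flag else 1] += 1
    return ContingencyTable(labels, np.array([counts[lbl] for lbl in labels]))


def cross_criteria_consistency(
    selections, threshold: int = 4, strict: bool = False
) -> bool:
    """Do the per-criterion best models for one alignment agree?

    With ``strict`` the best models must be identical across criteria;
    otherwise every pair must satisfy the similarity rule.  Invariant to
    the order of the selection records.
    """
    selections = list(selections)
    if len(selections) < 2:
        raise InvalidInputError("need at least two selection records")
    ids = {s.alignment_id for s in selections}
    if len(ids) > 1:
        raise InvalidInputError(f"selections come from different alignments: {ids}")
    best = [s.best for s in selections]
    if strict:
        return len(set(best)) == 1
    return all(
        similar_models(a, b, threshold)
        for i, a in enumerate(best)
        for b in best[i + 1 :]
    )
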