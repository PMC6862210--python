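"""Evaluation statistics for the two-class pair decision.

The positive class (+1) is "enzyme of the candidate class".  Per-class
correct rates, overall accuracy and the Matthews correlation coefficient are
computed from raw confusion counts; for a single discriminant function,
Wilks' lambda and the canonical correlation follow from the canonical
eigenvalue via Λ = 1/(1+λ) and R = sqrt(λ/(1+λ)).

Per-class rates are reported under neutral names (``rate_class_pos``,
``rate_class_neg``) rather than as sensitivity/specificity, because which
class counts as "positive" differs between conventions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/tn/fn for the two-class decision (positive class coded +1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def counts_from_labels(
    y_true: Iterable[int], y_pred: Iterable[int]
) -> ConfusionCounts:
    """Confusion counts from parallel ±1 label vectors."""
    yt = np.asarray(list(y_true), dtype=int)
    yp = np.asarray(list(y_pred), dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    if not set(np.unique(np.concatenate([yt, yp]))) <= {-1, 1}:
        raise ValueError("labels must be coded -1/+1")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == -1) & (yp == 1)).sum()),
        tn=int(((yt == -1) & (yp == -1)).sum()),
        fn=int(((yt == 1) & (yp == -1)).sum()),
    )


def per_class_rate(c: ConfusionCounts, cls: int) -> float:
    """Percent of class members classified correctly (full precision).

    ``cls=+1``: 100·tp/(tp+fn);  ``cls=−1``: 100·tn/(tn+fp).
    """
    if cls == 1:
        members = c.tp + c.fn
        correct = c.tp
    elif cls == -1:
        members = c.tn + c.fp
        correct = c.tn
    else:
        raise ValueError("class must be +1 or -1")
    if members == 0:
        raise ValueError(f"no members of class {cls:+d}")
    return 100.0 * correct / members


def accuracy(c: ConfusionCounts) -> float:
    """Overall percent correct: 100·(tp+tn)/total."""
    return 100.0 * (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [−1, 1].

    A zero marginal makes the denominator vanish; 0 is returned with a
    warning in that degenerate case.
    """
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        warnings.warn("a confusion-matrix marginal is zero; MCC reported as 0")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def wilks_from_eigenvalue(lmbda: float) -> tuple[float, float]:
    """(Wilks Λ, canonical R) from the canonical eigenvalue of one discriminant.

    Λ = 1/(1+λ)  and  R = sqrt(λ/(1+λ)); both identities hold only for a
    single discriminant function.
    """
    if lmbda < 0:
        raise ValueError("canonical eigenvalue must be non-negative")
    wilks = 1.0 / (1.0 + lmbda)
    canonical_r = math.sqrt(lmbda / (1.0 + lmbda))
    return wilks, canonical_r


def evaluation_report(counts_by_split: Mapping[str, ConfusionCounts]) -> dict:
    """Nested report (counts, per-class rates, accuracy, MCC) per split."""
    report: dict = {}
    for split, c in counts_by_split.items():
        entry: dict = {
            "counts": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
            "accuracy": accuracy(c),
            "mcc": mcc(c),
        }
        if c.tp + c.fn > 0:
            entry["rate_class_pos"] = per_class_rate(c, 1)
        if c.tn + c.fp > 0:
            entry["rate_class_neg"] = per_class_rate(c, -1)
        report[split] = entry
    return report
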