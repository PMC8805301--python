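"""Confusion-count bookkeeping and detector metrics.

Positives are ice-ring-contaminated plots or datasets.  Three metrics are
used throughout:

    accuracy    = (tp + tn) / (tp + fp + tn + fn)
    sensitivity = tp / (tp + fn)      (true-positive rate)
    specificity = tn / (tn + fp)      (true-negative rate)

Metric reports carry normal-approximation binomial 95% confidence
intervals; the CI is presentation only and is labelled with its method.
Datasets whose verdict is nonpredictable are excluded from the counts and
listed separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "binomial_ci_halfwidth",
    "evaluate_detector",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted: Sequence[bool], actual: Sequence[bool]) -> ConfusionCounts:
    """Cross-tabulate predicted vs actual labels (positive = contaminated)."""
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("empty label lists")
    return ConfusionCounts(
        tp=int((p & a).sum()),
        fp=int((p & ~a).sum()),
        tn=int((~p & ~a).sum()),
        fn=int((~p & a).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def binomial_ci_halfwidth(p: float, n: int) -> float:
    """Half-width of the 95% normal-approximation (Wald) binomial interval."""
    if n <= 0:
        return float("nan")
    return _Z95 * np.sqrt(p * (1.0 - p) / n)


def metric_row(c: ConfusionCounts) -> dict:
    """Counts plus the three metrics, each with its 95% CI half-width."""
    row: dict = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
    for name, fn, n in (
        ("accuracy", accuracy, c.total),
        ("sensitivity", sensitivity, c.tp + c.fn),
        ("specificity", specificity, c.tn + c.fp),
    ):
        try:
            val = fn(c)
            row[name] = val
            row[name + "_ci95"] = binomial_ci_halfwidth(val, n)
        except UndefinedMetricError:
            row[name] = float("nan")
            row[name + "_ci95"] = float("nan")
    return row


def evaluate_detector(
    verdicts: dict[str, str],
    gold: dict[str, bool],
    method: str = "detector",
) -> pd.DataFrame:
    """Dataset-level benchmark row from per-dataset verdicts and gold labels.

    ``verdicts`` maps dataset id -> "contaminated" | "clean" |
    "nonpredictable"; gold maps id -> True (contaminated) / False.
    Nonpredictable datasets are excluded from the confusion counts and
    reported in an ``n_excluded`` column.  Returns a one-row DataFrame in
    benchmark-table layout (counts, then metrics with Wald 95% CIs).
    """
    if not gold:
        raise ValueError("empty gold-label set")
    missing = set(gold) - set(verdicts)
    if missing:
        raise ValueError(f"no verdict for dataset(s): {sorted(missing)[:5]} ...")
    usable = [k for k in gold if verdicts[k] != "nonpredictable"]
    if not usable:
        raise ValueError("all datasets nonpredictable")
    pred = [verdicts[k] == "contaminated" for k in usable]
    act = [bool(gold[k]) for k in usable]
    row = {"method": method, **metric_row(confusion(pred, act))}
    row["n_excluded"] = len(gold) - len(usable)
    return pd.DataFrame([row])
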