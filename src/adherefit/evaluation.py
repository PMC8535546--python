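"""Adherence labelling rule and classification metrics.

A user is *non-adherent* (class 0) when they show no training activity over
the entire fourth month (days 91-120); any positive activity makes them
*adherent* (class 1, the positive class throughout).

Because regression forecasts are rarely exactly zero, a predicted month-4
series is binarised with a threshold tau on its 30-day total: the user is
predicted adherent iff the predicted monthly total is at least tau seconds.
An all-zero month is forecast with a bias floor on the order of 30 x the
SVR tube width (30 x epsilon = 300 s at the default epsilon = 10 s/day), so
tau must sit above that floor; the default tau = 600 s/month is twice the
floor yet still ~20x below typical adherent monthly activity (cohort daily
means run 300-400 s, i.e. ~10^4 s/month), keeping the rule faithful to
"essentially no activity at all".  tau is a configuration parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sessions_io import DailySeries, split_windows

__all__ = [
    "ADHERENT",
    "NON_ADHERENT",
    "DEFAULT_TAU",
    "ConfusionMatrix",
    "MetricsReport",
    "true_label",
    "predicted_label",
    "confusion",
    "metrics",
]

ADHERENT = "adherent"
NON_ADHERENT = "non_adherent"
DEFAULT_TAU = 600.0


def true_label(series: DailySeries) -> str:
    """Ground-truth adherence of a 120-day series from its fourth month."""
    _, test = split_windows(series)
    return NON_ADHERENT if np.all(test == 0.0) else ADHERENT


def predicted_label(pred_month4: Sequence[float], tau: float = DEFAULT_TAU) -> str:
    """Binarise a 30-day forecast: adherent iff its total is >= tau seconds."""
    pred = np.asarray(pred_month4, dtype=float)
    if pred.shape != (30,):
        raise ValueError(f"expected 30 predicted values, got shape {pred.shape}")
    if np.any(pred < 0):
        raise ValueError("predicted daily seconds must be non-negative")
    return ADHERENT if float(pred.sum()) >= tau else NON_ADHERENT


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with adherent (exercised in month 4) as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def pretty(self) -> str:
        """Tabular layout: rows actual no/yes, columns predicted no/yes."""
        rows = [
            ("Confusion Matrix", "Predicted: No", "Predicted: Yes"),
            ("Actual: No", f"TN: {self.tn}", f"FP: {self.fp}"),
            ("Actual: Yes", f"FN: {self.fn}", f"TP: {self.tp}"),
        ]
        widths = [max(len(r[c]) for r in rows) for c in range(3)]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
            for row in rows
        )


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics; a metric with a zero denominator is NaN."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float

    def defined(self, name: str) -> bool:
        return not math.isnan(getattr(self, name))

    def as_dict(self, ndigits: int | None = 4) -> dict[str, float]:
        out = {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "specificity": self.specificity,
            "f1": self.f1,
        }
        if ndigits is not None:
            out = {k: round(v, ndigits) for k, v in out.items()}
        return out


def confusion(true_labels: Sequence[str], pred_labels: Sequence[str]) -> ConfusionMatrix:
    """Tally the four cells over paired true/predicted label sequences."""
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"label sequences differ in length: {len(true_labels)} vs {len(pred_labels)}"
        )
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t == ADHERENT and p == ADHERENT:
            tp += 1
        elif t == NON_ADHERENT and p == NON_ADHERENT:
            tn += 1
        elif t == NON_ADHERENT and p == ADHERENT:
            fp += 1
        elif t == ADHERENT and p == NON_ADHERENT:
            fn += 1
        else:
            raise ValueError(f"unknown label pair ({t!r}, {p!r})")
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1 from a 2x2 matrix.

    accuracy    = (TP + TN) / N
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    f1          = 2 * precision * recall / (precision + recall)
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix (N = 0)")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.n,
        precision=precision,
        recall=recall,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        f1=f1,
    )
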