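"""Confusion matrix, accuracy indicators, and per-image judgement reports.

The lesion class is the positive class throughout (clinically standard:
a "positive" finding is the pathology).  Accuracy is the fraction of
correctly predicted images; sensitivity (= recall) the fraction of true
lesions detected; specificity the fraction of normals cleared; precision
the fraction of lesion calls that were right.  All indicators are
carried at double precision as percentages in [0, 100]; an indicator
with a zero denominator is reported as None rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dataset import LABELS

POSITIVE = "lesion"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    @property
    def recall(self) -> float | None:
        return self.sensitivity

    def as_dict(self) -> dict[str, float | None]:
        return {
            "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Precision": self.precision,
            "Recall": self.recall,
        }

    def to_text(self) -> str:
        rows = []
        for name, value in self.as_dict().items():
            rendered = "n/a" if value is None else f"{value:.2f}%"
            rows.append(f"{name:<12} {rendered}")
        return "\n".join(rows)


def confusion(predictions: Sequence[str], truth: Sequence[str]) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix with lesion as the positive class."""
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    if len(truth) == 0:
        raise ValueError("cannot tally an empty prediction list")
    for label in list(predictions) + list(truth):
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
    tp = fn = fp = tn = 0
    for p, t in zip(predictions, truth):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fn, fp, tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Indicator set derived from a confusion matrix (percentages)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return MetricsReport(
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
    )


def accuracy_percent(correct: int, total: int) -> float:
    """Correctly predicted images over total images, as a percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must be between 0 and total")
    return 100.0 * correct / total


def format_verdict(probs: Sequence[float], class_names: Sequence[str] = LABELS,
                   display_names: dict[str, str] | None = None) -> str:
    """Render "<p>% to be <label>" with p at one decimal; ties take class 0."""
    display = {"normal": "normal", "lesion": "apical lesion"}
    if display_names:
        display.update(display_names)
    best = 0
    for i, p in enumerate(probs):
        if p > probs[best]:
            best = i
    return f"{100.0 * probs[best]:.1f}% to be {display[class_names[best]]}"


def report_judgements(
    predictions: Sequence[tuple[str, Sequence[float]]],
    clinical: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per image: id, clinical label (if known), verdict string."""
    rows = []
    for image_id, probs in predictions:
        rows.append({
            "Image": image_id,
            "Clinical Data": (clinical or {}).get(image_id, ""),
            "Judgement": format_verdict(probs),
        })
    return pd.DataFrame(rows, columns=["Image", "Clinical Data", "Judgement"])


def confusion_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Counts plus row-normalized percentages, lesion-positive."""
    def pct(n, d):
        return f"{100.0 * n / d:.2f}%" if d else "n/a"

    n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
    return pd.DataFrame(
        {
            "Predicted normal": [cm.tn, cm.fn,
                                 pct(cm.tn, n_neg), pct(cm.fn, n_pos)],
            "Predicted lesion": [cm.fp, cm.tp,
                                 pct(cm.fp, n_neg), pct(cm.tp, n_pos)],
        },
        index=["True normal (count)", "True lesion (count)",
               "True normal (%)", "True lesion (%)"],
    )


def save_metrics(report: MetricsReport, path: str | Path) -> None:
    pd.DataFrame([report.as_dict()]).to_csv(path, index=False)
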