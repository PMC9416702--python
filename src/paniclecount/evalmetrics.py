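"""Detection-evaluation indicators for counting pipelines.

Detections are matched one-to-one to ground-truth boxes by greedy
IoU matching, yielding TP/FP/FN counts (TN is fixed at zero: the
background is never an explicit detection class, so there are no true
negatives).  From these, six indicators are computed on the percentage
scale used in field-phenotyping reports:

* MAPE — mean absolute percentage error of per-image counts,
  ``mean(|y_i - yhat_i| / y_i) * 100``.
* Precision ``TP/(TP+FP)``, Recall ``TP/(TP+FN)``, and their harmonic
  mean F.
* Accuracy ``(TP+TN)/(TP+TN+FP+FN)`` which, with TN = 0, reduces to the
  critical success index ``TP/(TP+FP+FN)``.
* R² — squared Pearson correlation between machine and manual counts
  (the R² of the least-squares fit of machine on manual, not the
  identity-line R²).
* Counting accuracy ``P_c = N_cor / N_real * 100`` where ``N_cor`` is
  the number of correctly detected objects and ``N_real`` the true
  object count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxgeom import Box, iou


class MetricInputError(ValueError):
    """Raised when a metric is undefined for the given input."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN for one evaluation run; TN is zero by convention.

    ``n_cor`` aliases ``tp`` (correctly detected objects) and ``n_real``
    is the ground-truth object count, so ``tp + fn = n_real``.
    """

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise MetricInputError("confusion counts must be non-negative")

    @property
    def n_cor(self) -> int:
        return self.tp

    @property
    def n_real(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class CountSeries:
    """Paired manual (y_i) and machine (yhat_i) counts across n images."""

    manual: tuple[float, ...]
    machine: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.manual) != len(self.machine):
            raise MetricInputError("manual and machine series differ in length")
        if len(self.manual) < 1:
            raise MetricInputError("need at least one image")

    @property
    def n(self) -> int:
        return len(self.manual)


def match_detections(
    pred: Sequence[Box], gt: Sequence[Box], match_iou: float = 0.5
) -> ConfusionCounts:
    """Greedily match predictions to ground truth, one-to-one.

    Predictions are visited in descending score (descending area as the
    fallback when scores are absent or tie); each is assigned to the
    unmatched ground-truth box with the highest IoU, provided that IoU
    is at least ``match_iou``.  TP = matched predictions, FP = unmatched
    predictions, FN = unmatched ground truth.
    """
    if not (0.0 < match_iou <= 1.0):
        raise MetricInputError(f"match_iou {match_iou} outside (0, 1]")

    def rank(b: Box) -> tuple:
        score = b.score if b.score is not None else -1.0
        return (-score, -b.area, b.corner_key())

    unmatched = list(range(len(gt)))
    tp = 0
    for p in sorted(pred, key=rank):
        best_j = -1
        best_iou = 0.0
        for j in unmatched:
            if p.area <= 0.0 and gt[j].area <= 0.0:
                continue
            v = iou(p, gt[j])
            if v > best_iou:
                best_iou = v
                best_j = j
        if best_j >= 0 and best_iou >= match_iou:
            unmatched.remove(best_j)
            tp += 1
    return ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(unmatched))


def mape(series: CountSeries) -> float:
    """Mean absolute percentage error, on the 0-100 scale."""
    manual = np.asarray(series.manual, dtype=float)
    machine = np.asarray(series.machine, dtype=float)
    if np.any(manual <= 0):
        raise MetricInputError("MAPE undefined: a manual count is zero")
    return float(np.mean(np.abs(manual - machine) / manual) * 100.0)


def precision_recall_f(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F-measure as percentages."""
    if counts.tp + counts.fp == 0:
        raise MetricInputError("precision undefined: no predictions (tp+fp=0)")
    if counts.tp + counts.fn == 0:
        raise MetricInputError("recall undefined: no ground truth (tp+fn=0)")
    precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    recall = 100.0 * counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0.0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f


def accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN)/(TP+TN+FP+FN) as a percentage; with TN = 0 this is the
    critical success index TP/(TP+FP+FN)."""
    denom = counts.tp + counts.tn + counts.fp + counts.fn
    if denom == 0:
        raise MetricInputError("accuracy undefined: all counts zero")
    return 100.0 * (counts.tp + counts.tn) / denom


def r_squared(series: CountSeries) -> float:
    """Squared Pearson correlation between machine and manual counts."""
    if series.n < 2:
        raise MetricInputError("R^2 undefined: need at least two images")
    manual = np.asarray(series.manual, dtype=float)
    machine = np.asarray(series.machine, dtype=float)
    if np.ptp(manual) == 0 or np.ptp(machine) == 0:
        raise MetricInputError("R^2 undefined: zero variance in a series")
    r = np.corrcoef(manual, machine)[0, 1]
    return float(r * r)


def counting_accuracy_pc(counts: ConfusionCounts) -> float:
    """Counting accuracy P_c = 100 * N_cor / N_real."""
    if counts.n_real == 0:
        raise MetricInputError("P_c undefined: no ground-truth objects")
    return 100.0 * counts.n_cor / counts.n_real
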