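"""Detection evaluation: confusion matrices, the five standard metrics,
and recall-versus-threshold curves.

Detection outcomes are scored per image: TP — the animal was located
and is present; TN — not located and absent; FP — located but absent;
FN — not located but present.  From the counts:

    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    F-measure   = 2 TP / (2 TP + FN + FP)

A zero denominator makes the metric *undefined* (reported as ``None``),
never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """The five metrics; ``None`` marks an undefined (0/0) value."""

    specificity: float | None
    accuracy: float | None
    precision: float | None
    recall: float | None
    f_measure: float | None

    def rounded(self, decimals: int = 2) -> dict:
        """Display rounding (reports use 2 decimals); raw values stay
        available on the attributes."""
        return {
            k: (None if v is None else round(v, decimals))
            for k, v in self.__dict__.items()
        }


def build_confusion(predictions, truth) -> ConfusionMatrix:
    """Count detection outcomes against per-image ground truth.

    ``predictions`` holds per-image located-or-not booleans (or mappings
    with a ``"located"`` key); ``truth`` holds animal-present booleans
    (or mappings with an ``"animal_present"`` key).
    """
    pred = [p["located"] if isinstance(p, dict) else bool(p) for p in predictions]
    pres = [t["animal_present"] if isinstance(t, dict) else bool(t) for t in truth]
    if len(pred) != len(pres):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(pres)} truths")
    pred_a = np.asarray(pred, dtype=bool)
    pres_a = np.asarray(pres, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(pred_a & pres_a)),
        fp=int(np.sum(pred_a & ~pres_a)),
        fn=int(np.sum(~pred_a & pres_a)),
        tn=int(np.sum(~pred_a & ~pres_a)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """The five detection metrics from one confusion matrix."""
    return MetricReport(
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        recall=_ratio(cm.tp, cm.tp + cm.fn),
        f_measure=_ratio(2 * cm.tp, 2 * cm.tp + cm.fn + cm.fp),
    )


def recall_curve(scored, thresholds) -> list[tuple[float, float]]:
    """Recall of the rule "detect iff score >= t" over a threshold grid.

    ``scored`` is a sequence of ``(score, truth)`` pairs; only the
    positive samples enter the recall.  Computed in a single pass over
    the sorted positive scores.  The curve is non-increasing in the
    threshold under this (standard) convention.
    """
    scored = list(scored)
    if not scored:
        return []
    thresholds = np.asarray(list(thresholds), dtype=np.float64)
    if thresholds.size and np.any(np.diff(thresholds) < 0):
        raise ValueError("threshold grid must be sorted ascending")
    pos_scores = np.sort([s for s, t in scored if t])
    n_pos = pos_scores.size
    if n_pos == 0:
        return [(float(t), 0.0) for t in thresholds]
    # recall(t) = #(positive scores >= t) / n_pos
    n_below = np.searchsorted(pos_scores, thresholds, side="left")
    return [(float(t), float((n_pos - nb) / n_pos)) for t, nb in zip(thresholds, n_below)]


def curve_auc(curve) -> float:
    """Trapezoidal area under an emitted (threshold, recall) curve."""
    if len(curve) < 2:
        return 0.0
    t, r = zip(*curve)
    return float(np.trapezoid(r, t))
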