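"""Agreement metrics between predicted and expert drop labels.

Evaluation is restricted to the classified points (falling edges with a valid
feature row).  Each point is one of:

* true 'drop'        — predicted and expert-labelled drop;
* false 'no drop'    — expert drop the classifier missed;
* true 'no drop'     — both agree no drop;
* false 'drop'       — predicted drop the expert did not mark.

A predicted drop that *precedes* an expert interval on the same contiguous
falling run (no intervening rise before the interval starts) is an early
detection: the machine called the drop before the human would, which is
desirable, so such points are credited as true 'drops' rather than penalised
as false 'drops'.

Sensitivity = TD / (TD + FND); specificity = TND / (TND + FD);
accuracy = (TD + TND) / all evaluated falling-edge points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DropAnnotation

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "reclassify_early",
    "count_confusion",
    "compute_metrics",
    "evaluate_series",
]

TD, FND, TND, FD = "TD", "FND", "TND", "FD"


@dataclass(frozen=True)
class ConfusionCounts:
    true_drops: int = 0
    false_no_drops: int = 0
    true_no_drops: int = 0
    false_drops: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.true_drops + other.true_drops,
            self.false_no_drops + other.false_no_drops,
            self.true_no_drops + other.true_no_drops,
            self.false_drops + other.false_drops,
        )

    @property
    def total(self) -> int:
        return self.true_drops + self.false_no_drops + self.true_no_drops + self.false_drops


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float


def reclassify_early(
    pred: np.ndarray,
    annotation: DropAnnotation | np.ndarray,
    cm_amp: np.ndarray,
    falling: np.ndarray,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Per-point agreement outcomes with early-detection credit.

    Returns an array of outcome codes ('TD', 'FND', 'TND', 'FD') over the
    evaluated points and '' elsewhere.  ``eligible`` defaults to the falling
    mask; pass ``valid & falling`` to skip points without feature vectors.

    A predicted drop at an expert 'no drop' point is upgraded to TD when some
    expert interval starts later on the same contiguous falling run — every
    point strictly between the prediction and the interval start is itself on
    a falling edge, so no local peak intervenes.
    """
    pred = np.asarray(pred, dtype=bool)
    cm_amp = np.asarray(cm_amp, dtype=float)
    falling = np.asarray(falling, dtype=bool)
    n = pred.size
    if isinstance(annotation, DropAnnotation):
        expert = annotation.labels(n)
        starts = [a for a, _ in annotation.intervals]
    else:
        expert = np.asarray(annotation, dtype=bool)
        starts = [
            t for t in range(n) if expert[t] and (t == 0 or not expert[t - 1])
        ]
    if eligible is None:
        eligible = falling
    eligible = np.asarray(eligible, dtype=bool)
    if not (cm_amp.shape == falling.shape == pred.shape == expert.shape):
        raise ValueError("pred, labels, cm_amp and masks must be aligned")

    out = np.full(n, "", dtype="<U4")
    for t in range(n):
        if not eligible[t]:
            continue
        if pred[t] and expert[t]:
            out[t] = TD
        elif not pred[t] and expert[t]:
            out[t] = FND
        elif not pred[t] and not expert[t]:
            out[t] = TND
        else:
            early = any(
                s > t and falling[t + 1 : s + 1].all() for s in starts
            )
            out[t] = TD if early else FD
    return out


def count_confusion(outcomes: np.ndarray) -> ConfusionCounts:
    """Tally outcome codes into confusion counts."""
    outcomes = np.asarray(outcomes)
    return ConfusionCounts(
        true_drops=int((outcomes == TD).sum()),
        false_no_drops=int((outcomes == FND).sum()),
        true_no_drops=int((outcomes == TND).sum()),
        false_drops=int((outcomes == FD).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy from confusion counts.

    A metric whose denominator is zero is undefined and reported as NaN.
    """

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return Metrics(
        sensitivity=_ratio(counts.true_drops, counts.true_drops + counts.false_no_drops),
        specificity=_ratio(counts.true_no_drops, counts.true_no_drops + counts.false_drops),
        accuracy=_ratio(counts.true_drops + counts.true_no_drops, counts.total),
    )


def evaluate_series(
    pred: np.ndarray,
    annotation: DropAnnotation | np.ndarray,
    cm_amp: np.ndarray,
    falling: np.ndarray,
    eligible: np.ndarray | None = None,
) -> ConfusionCounts:
    """Convenience: outcomes with early credit, tallied to counts."""
    return count_confusion(reclassify_early(pred, annotation, cm_amp, falling, eligible))
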