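"""Pixel-wise segmentation metrics for binary masks.

Given a segmentation S and ground truth G over N pixels, the confusion
counts are TP = sum(S*G), TN = sum((1-S)(1-G)), FP = sum(S(1-G)),
FN = sum((1-S)G), from which follow sensitivity Se = TP/(TP+FN),
specificity Sp = TN/(TN+FP), accuracy A = (TP+TN)/N, balanced accuracy
BA = (Se+Sp)/2, Dice/F1 D = 2TP/(2TP+FP+FN), Jaccard J = TP/(TP+FP+FN)
and overlap error E = 1-J.  All metrics live in [0, 1].

Vanishing denominators follow the conventions: Se = 1 when there is no
ground-truth foreground, Sp = 1 when there is no ground-truth background,
and D = J = 1 (E = 0) when both masks are empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "MetricSet",
    "confusion_counts",
    "metrics_from_counts",
    "evaluate_masks",
    "jaccard_to_error",
    "dice_from_jaccard",
    "class_imbalance",
]

METRIC_NAMES = ("se", "sp", "a", "ba", "dice", "jaccard", "error")


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts plus the seven derived metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    se: float
    sp: float
    a: float
    ba: float
    dice: float
    jaccard: float
    error: float

    @property
    def n_pixels(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "se": self.se, "sp": self.sp, "a": self.a, "ba": self.ba,
            "dice": self.dice, "jaccard": self.jaccard, "error": self.error,
        }


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def confusion_counts(
    segmented: np.ndarray, reference: np.ndarray
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) pixel counts of *segmented* against *reference*."""
    s = _as_binary(segmented, "segmented")
    g = _as_binary(reference, "reference")
    if s.shape != g.shape:
        raise ValidationError(
            f"shape mismatch: segmented {s.shape} vs reference {g.shape}"
        )
    tp = int(np.count_nonzero(s & g))
    tn = int(np.count_nonzero(~s & ~g))
    fp = int(np.count_nonzero(s & ~g))
    fn = int(np.count_nonzero(~s & g))
    return tp, tn, fp, fn


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> MetricSet:
    """Compute the seven metrics from confusion counts."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValidationError(f"count {name} is negative: {v}")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValidationError("all confusion counts are zero")
    se = tp / (tp + fn) if tp + fn > 0 else 1.0
    sp = tn / (tn + fp) if tn + fp > 0 else 1.0
    a = (tp + tn) / n
    ba = (se + sp) / 2.0
    union = tp + fp + fn
    if union > 0:
        jaccard = tp / union
        dice = 2 * tp / (2 * tp + fp + fn)
    else:  # both masks empty
        jaccard = dice = 1.0
    return MetricSet(
        tp=tp, tn=tn, fp=fp, fn=fn,
        se=se, sp=sp, a=a, ba=ba,
        dice=dice, jaccard=jaccard, error=1.0 - jaccard,
    )


def evaluate_masks(segmented: np.ndarray, reference: np.ndarray) -> MetricSet:
    """Score a segmentation against a reference mask."""
    return metrics_from_counts(*confusion_counts(segmented, reference))


def jaccard_to_error(j: float) -> float:
    """Overlap error E = 1 - J."""
    if not 0.0 <= j <= 1.0:
        raise ValidationError(f"Jaccard value out of [0, 1]: {j}")
    return 1.0 - j


def dice_from_jaccard(j: float) -> float:
    """Closed-form conversion D = 2J/(1+J)."""
    if not 0.0 <= j <= 1.0:
        raise ValidationError(f"Jaccard value out of [0, 1]: {j}")
    return 2.0 * j / (1.0 + j)


def class_imbalance(mask: np.ndarray) -> tuple[float, float]:
    """(%foreground, %background) pixel percentages, summing to 100."""
    m = _as_binary(mask, "mask")
    if m.size == 0:
        raise ValidationError("mask is empty")
    fg = 100.0 * np.count_nonzero(m) / m.size
    return fg, 100.0 - fg
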