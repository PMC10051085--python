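"""Pixelwise segmentation metrics: confusion counts, Dice, Jaccard, accuracy.

For predicted mask A and ground truth B,

    Dice(A, B)    = 2|A n B| / (|A| + |B|)
    Jaccard(A, B) = |A n B| / |A u B|
    Accuracy      = (TP + TN) / (TP + FP + FN + TN)

with the convention Dice = Jaccard = 1 when both masks are empty (perfect
agreement; avoids 0/0). Dice and Jaccard are related by D = 2J / (1 + J),
so J <= D always. Dataset evaluation reports both the per-image mean of
each metric (the headline) and the metrics of the pooled confusion counts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice_coefficient",
    "jaccard_index",
    "pixel_accuracy",
    "evaluate_dataset",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def _check_pair(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"mask dimension mismatch: {pred.shape} vs {true.shape}")
    for name, m in (("pred", pred), ("true", true)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    return pred.astype(bool), true.astype(bool)


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of a predicted mask against ground truth."""
    pred, true = _check_pair(pred_mask, true_mask)
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|AnB|/(|A|+|B|); 1.0 when both masks are empty."""
    pred, true = _check_pair(pred_mask, true_mask)
    a, b = np.count_nonzero(pred), np.count_nonzero(true)
    if a + b == 0:
        return 1.0
    inter = np.count_nonzero(pred & true)
    return 2.0 * inter / (a + b)


def jaccard_index(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Jaccard / IoU |AnB|/|AuB|; 1.0 when both masks are empty."""
    pred, true = _check_pair(pred_mask, true_mask)
    union = np.count_nonzero(pred | true)
    if union == 0:
        return 1.0
    inter = np.count_nonzero(pred & true)
    return inter / union


def pixel_accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correctly classified pixels, (TP+TN)/total."""
    if counts.total <= 0:
        raise ValueError("cannot compute accuracy over zero pixels")
    return (counts.tp + counts.tn) / counts.total


@dataclass
class MetricsReport:
    """Dataset-level evaluation summary.

    ``accuracy``/``dice``/``jaccard`` are means over images;
    ``pooled_dice``/``pooled_jaccard`` are computed from the summed
    confusion counts over all pixels.
    """

    accuracy: float
    dice: float
    jaccard: float
    counts: ConfusionCounts
    n_images: int
    pooled_dice: float = float("nan")
    pooled_jaccard: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "dice": self.dice,
            "jaccard": self.jaccard,
            "pooled_dice": self.pooled_dice,
            "pooled_jaccard": self.pooled_jaccard,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "n_images": self.n_images,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_csv(self, path: str | Path) -> None:
        cols = ["accuracy", "dice", "jaccard", "tp", "tn", "fp", "fn", "n_images"]
        d = self.to_dict()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            writer.writerow([d[c] for c in cols])


def _pooled_overlap(counts: ConfusionCounts) -> tuple[float, float]:
    denom_d = 2 * counts.tp + counts.fp + counts.fn
    denom_j = counts.tp + counts.fp + counts.fn
    dice = 2 * counts.tp / denom_d if denom_d else 1.0
    jac = counts.tp / denom_j if denom_j else 1.0
    return dice, jac


def evaluate_dataset(model, samples, threshold: float = 0.5) -> MetricsReport:
    """Evaluate a segmentation model over a list of :class:`ImageSample`.

    Predictions are binarized at ``threshold``; per-image Dice/Jaccard/
    accuracy are averaged and the pooled confusion counts reported
    alongside.
    """
    from .models import predict_mask  # local import to avoid a cycle

    if not samples:
        raise ValueError("cannot evaluate an empty sample list")
    dices, jacs, accs = [], [], []
    pooled = ConfusionCounts()
    for s in samples:
        pred = predict_mask(model, s.image, threshold=threshold)
        c = confusion(pred, s.mask)
        pooled = pooled + c
        dices.append(dice_coefficient(pred, s.mask))
        jacs.append(jaccard_index(pred, s.mask))
        accs.append(pixel_accuracy(c))
    pooled_dice, pooled_jac = _pooled_overlap(pooled)
    return MetricsReport(
        accuracy=float(np.mean(accs)),
        dice=float(np.mean(dices)),
        jaccard=float(np.mean(jacs)),
        counts=pooled,
        n_images=len(samples),
        pooled_dice=pooled_dice,
        pooled_jaccard=pooled_jac,
    )
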