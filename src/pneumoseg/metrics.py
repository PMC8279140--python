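"""Segmentation evaluation metrics.

IoU and Dice are reported per image and macro-averaged; pixel confusion
metrics (accuracy, precision, recall, F-measure) are micro-averaged over
the pooled pixels of an image set.  The competition convention applies:
when prediction and ground truth are both empty, the per-image Dice (and,
by the same reasoning, IoU) is 1 — a correct negative, not a miss.  PSNR
is computed on masks rescaled to {0, 255} with peak value 255.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "iou",
    "dsc",
    "mean_iou",
    "mean_dsc",
    "confusion",
    "confusion_rates",
    "psnr_db",
    "evaluate_masks",
]


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred != 0, truth != 0


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; defined as 1.0 when both masks are empty."""
    p, t = _check_pair(pred, truth)
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y|/(|X|+|Y|); 1.0 when both empty."""
    p, t = _check_pair(pred, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def _mean_over(fn, preds, truths) -> float:
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError(f"list length mismatch: {len(preds)} vs {len(truths)}")
    if not preds:
        raise ValueError("empty mask lists")
    return float(np.mean([fn(p, t) for p, t in zip(preds, truths)]))


def mean_dsc(preds, truths) -> float:
    """Per-image Dice averaged over an image set (the competition score)."""
    return _mean_over(dsc, preds, truths)


def mean_iou(preds, truths) -> float:
    """Per-image IoU averaged over an image set (the tuning objective)."""
    return _mean_over(iou, preds, truths)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts for one mask pair."""
    p, t = _check_pair(pred, truth)
    return ConfusionCounts(
        tp=int(np.logical_and(p, t).sum()),
        fp=int(np.logical_and(p, ~t).sum()),
        fn=int(np.logical_and(~p, t).sum()),
        tn=int(np.logical_and(~p, ~t).sum()),
    )


def confusion_rates(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F-measure from pooled pixel counts.

    Precision and recall return 0 when their denominator is 0.
    """
    def _ratio(num, den):
        return num / den if den else 0.0

    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "precision": _ratio(c.tp, c.tp + c.fp),
        "recall": _ratio(c.tp, c.tp + c.fn),
        "f_measure": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def psnr_db(pred: np.ndarray, truth: np.ndarray, *, cap_db: float = math.inf) -> float:
    """Peak signal-to-noise ratio between binary masks rescaled to {0, 255}.

    20*log10(255/sqrt(MSE)).  Identical masks have zero MSE; the return
    value is then ``cap_db`` (+inf by default, a documented sentinel).
    """
    p, t = _check_pair(pred, truth)
    mse = float(np.mean((p.astype(np.float64) * 255 - t.astype(np.float64) * 255) ** 2))
    if mse == 0.0:
        return cap_db
    return 20.0 * math.log10(255.0 / math.sqrt(mse))


@dataclass
class MetricReport:
    iou: float
    mean_dsc: float
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    psnr_db: float
    n_images: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_masks(preds, truths, *, psnr_cap_db: float = math.inf) -> MetricReport:
    """Full metric report for aligned lists of predicted and true masks.

    IoU/DSC are macro (per-image mean, both-empty = 1); confusion rates are
    micro (pixel-pooled); PSNR is the per-image mean, with identical pairs
    contributing ``psnr_cap_db``.
    """
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError(f"list length mismatch: {len(preds)} vs {len(truths)}")
    if not preds:
        raise ValueError("empty mask lists")
    pooled = ConfusionCounts()
    for p, t in zip(preds, truths):
        pooled = pooled + confusion(p, t)
    rates = confusion_rates(pooled)
    return MetricReport(
        iou=mean_iou(preds, truths),
        mean_dsc=mean_dsc(preds, truths),
        psnr_db=float(np.mean([psnr_db(p, t, cap_db=psnr_cap_db) for p, t in zip(preds, truths)])),
        n_images=len(preds),
        **rates,
    )
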