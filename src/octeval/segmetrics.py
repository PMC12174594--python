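"""Per-class segmentation metrics: recall, precision, IOU, Dice.

Predicted masks are scored against gold masks by exact per-pixel
cross-tabulation.  For class ``c`` with true positives TP, false
positives FP and false negatives FN:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    IOU       = TP / (TP + FP + FN)
    Dice      = 2·TP / (2·TP + FP + FN) = 2·IOU / (1 + IOU)

Classes absent from both gold and prediction are undefined (``nan``)
and excluded from the unweighted macro average.  Whether a published
"Average" row is pixel-weighted is often unstated; the unweighted macro
convention used here is recorded in output metadata.  Report tables
label the precision column "precision (reported elsewhere as
'Accuracy')" where compatibility with that naming is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PixelConfusion", "ClassMetrics", "pixel_confusion",
           "class_metrics", "metrics_frame"]


@dataclass(frozen=True)
class PixelConfusion:
    """K×K pixel count grid; rows = gold class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion counts must be square")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pixel_confusion(
    gold_mask: np.ndarray, pred_mask: np.ndarray, n_classes: int = 3
) -> PixelConfusion:
    """Exact pixel-wise cross-tabulation of two label masks."""
    gold = np.asarray(gold_mask)
    pred = np.asarray(pred_mask)
    if gold.shape != pred.shape:
        raise ValueError(
            f"mask shapes differ: {gold.shape} vs {pred.shape}")
    if gold.size == 0:
        raise ValueError("empty masks")
    for name, m in (("gold", gold), ("pred", pred)):
        if m.min() < 0 or m.max() >= n_classes:
            raise ValueError(f"{name} mask labels must lie in [0, {n_classes})")
    flat = gold.astype(np.int64).ravel() * n_classes + pred.astype(np.int64).ravel()
    counts = np.bincount(flat, minlength=n_classes * n_classes)
    return PixelConfusion(counts.reshape(n_classes, n_classes))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class and macro metrics; undefined entries are ``nan``."""

    recall: np.ndarray
    precision: np.ndarray
    iou: np.ndarray
    dice: np.ndarray

    def macro(self, metric: str) -> float:
        values = getattr(self, metric)
        if np.all(np.isnan(values)):
            return float("nan")
        return float(np.nanmean(values))

    def as_dict(self) -> dict[str, list[float]]:
        return {m: [float(v) for v in getattr(self, m)]
                for m in ("recall", "precision", "iou", "dice")}


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def class_metrics(conf: PixelConfusion) -> ClassMetrics:
    """Recall, precision, IOU and Dice per class from a confusion grid.

    A class with no gold pixels has undefined recall; one never
    predicted has undefined precision; a class absent from both has all
    four undefined.
    """
    counts = conf.counts.astype(float)
    tp = np.diag(counts)
    gold_tot = counts.sum(axis=1)   # TP + FN
    pred_tot = counts.sum(axis=0)   # TP + FP
    union = gold_tot + pred_tot - tp
    return ClassMetrics(
        recall=_ratio(tp, gold_tot),
        precision=_ratio(tp, pred_tot),
        iou=_ratio(tp, union),
        dice=_ratio(2 * tp, gold_tot + pred_tot),
    )


def metrics_frame(
    gold_mask: np.ndarray,
    pred_mask: np.ndarray,
    n_classes: int = 3,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Metric table with one row per class plus an unweighted average.

    Column order matches the conventional report layout (recall,
    precision, IOU, Dice); the average row skips undefined classes.
    """
    m = class_metrics(pixel_confusion(gold_mask, pred_mask, n_classes))
    names = class_names or [f"class {k}" for k in range(n_classes)]
    df = pd.DataFrame(
        {
            "recall": m.recall,
            "precision": m.precision,
            "iou": m.iou,
            "dice": m.dice,
        },
        index=names,
    )
    df.loc["average"] = [m.macro(c) for c in df.columns]
    df.attrs["average"] = "unweighted macro over defined classes"
    return df
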