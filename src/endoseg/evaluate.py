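"""Per-pixel evaluation: confusion counts, accuracy, ROC curves, reports.

Accuracy is the strict per-pixel fraction of correctly classified pixels,

    Accuracy% = 100 * (TP + TN) / (TP + TN + FP + FN),

with boundary as the positive class.  ROC points are built by sweeping a
method's operating setting (a threshold family for the classical methods, a
(C, gamma) search for the SVM) and recording (FPR, TPR) per setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    """Pixel confusion counts; boundary = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0


def confusion(pred, truth, region: Optional[np.ndarray] = None) -> ConfusionCounts:
    """Confusion counts of a predicted mask against ground truth.

    ``region`` optionally restricts evaluation to a boolean subset of pixels
    (e.g. to exclude a border margin).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if region is not None:
        region = np.asarray(region).astype(bool)
        pred, truth = pred[region], truth[region]
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp, fp, tn, fn)


def accuracy(counts: ConfusionCounts) -> float:
    """Per-pixel accuracy in percent."""
    if counts.total == 0:
        raise ValueError("no pixels evaluated")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def mask_accuracy(pred, truth, region: Optional[np.ndarray] = None) -> float:
    """Convenience: accuracy (%) of a mask pair."""
    return accuracy(confusion(pred, truth, region))


@dataclass
class RocCurve:
    """(FPR, TPR) points with their setting descriptors, sorted by FPR."""

    method: str
    points: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def fpr(self) -> np.ndarray:
        return self.points["fpr"].to_numpy()

    @property
    def tpr(self) -> np.ndarray:
        return self.points["tpr"].to_numpy()


def roc_from_sweep(masks_with_settings, truth, method: str = "") -> RocCurve:
    """Build an ROC curve from a family of masks.

    Parameters
    ----------
    masks_with_settings : sequence of (mask, setting) pairs
    truth : ground-truth boundary mask

    Duplicate (FPR, TPR) points are collapsed (keeping the first setting)
    and the result is sorted by FPR then TPR.
    """
    if len(masks_with_settings) == 0:
        raise ValueError("need at least one mask")
    rows = []
    for mask, setting in masks_with_settings:
        c = confusion(mask, truth)
        rows.append({"fpr": c.fpr, "tpr": c.tpr, "setting": setting})
    df = pd.DataFrame(rows)
    df = df.drop_duplicates(subset=["fpr", "tpr"], keep="first")
    df = df.sort_values(["fpr", "tpr"], kind="stable").reset_index(drop=True)
    return RocCurve(method=method, points=df)


def comparison_report(
    methods: Sequence[tuple],
    images: Sequence[tuple],
) -> pd.DataFrame:
    """Accuracy table: one row per method, one column per image plus 'mean'.

    ``methods`` is a sequence of ``(name, segment_fn)`` where ``segment_fn``
    maps an image to a binary boundary mask at the method's operating point
    (trained SVM; automatic Otsu/Kittler threshold; a fixed Canny setting).
    ``images`` is a sequence of ``(image, truth_mask)`` pairs.  Failures in a
    cell record NaN and the report continues.
    """
    if len(methods) == 0 or len(images) == 0:
        raise ValueError("need at least one method and one image")
    cols = [f"image_{k}" for k in range(len(images))]
    table = pd.DataFrame(index=[name for name, _ in methods], columns=cols, dtype=float)
    table.index.name = "method"
    for name, fn in methods:
        for k, (img, truth) in enumerate(images):
            try:
                table.loc[name, cols[k]] = mask_accuracy(fn(img), truth)
            except Exception:
                table.loc[name, cols[k]] = np.nan
    table["mean"] = table[cols].mean(axis=1)
    return table


def format_report(table: pd.DataFrame) -> str:
    """Plain-text rendering of a comparison table (method, Accuracy%)."""
    lines = ["Method\tAccuracy%"]
    for name, row in table.iterrows():
        lines.append(f"{name}\t{row['mean']:.2f}")
    return "\n".join(lines)
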