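"""Segmentation metrics and the cross-validation protocol.

Metrics are confusion-matrix based with IGNORE pixels excluded from every
tally.  "Mean" pixel accuracy and IoU are class-weighted averages; because
that phrase admits two readings, both are available — frequency weighting
(weights = true-class pixel shares, the default) and the plain unweighted
macro mean — and reports carry the weighting they used.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from . import sig
from .types import IGNORE, N_CLASSES


@dataclass
class EvalReport:
    """Per-class and aggregated segmentation quality in [0, 1]."""

    per_class_accuracy: np.ndarray
    per_class_iou: np.ndarray
    mAcc: float
    mIoU: float
    weighting: str
    support: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": [None if np.isnan(v) else float(v) for v in self.per_class_accuracy],
            "per_class_iou": [None if np.isnan(v) else float(v) for v in self.per_class_iou],
            "mAcc": self.mAcc,
            "mIoU": self.mIoU,
            "weighting": self.weighting,
            "support": self.support.tolist(),
        }


def confusion(pred: np.ndarray, truth: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """C x C counts (rows = true class, cols = predicted); IGNORE excluded."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    valid = truth != IGNORE
    t = truth[valid].astype(np.int64)
    p = pred[valid].astype(np.int64)
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("class values outside [0, n_classes)")
    return np.bincount(t * n_classes + p, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def metrics(cm: np.ndarray, weighting: str = "frequency") -> EvalReport:
    """Per-class accuracy/IoU and their aggregate under the chosen weighting.

    Accuracy_c = diag/row-sum; IoU_c = diag/(row-sum + col-sum - diag).
    Classes with zero support (empty rows) are excluded from aggregates.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    if weighting not in ("frequency", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    supported = row > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = np.where(supported, diag / row, np.nan)
        union = row + col - diag
        iou = np.where(supported, np.where(union > 0, diag / np.maximum(union, 1e-300), np.nan), np.nan)
    if weighting == "frequency":
        w = row[supported] / row[supported].sum()
    else:
        w = np.full(supported.sum(), 1.0 / supported.sum())
    macc = float(np.sum(w * acc[supported]))
    miou = float(np.sum(w * iou[supported]))
    return EvalReport(
        per_class_accuracy=acc,
        per_class_iou=iou,
        mAcc=macc,
        mIoU=miou,
        weighting=weighting,
        support=row.astype(np.int64),
    )


def full_report(cm: np.ndarray) -> dict:
    """Both weightings of the same confusion matrix, JSON-ready."""
    return {
        "frequency": metrics(cm, "frequency").to_dict(),
        "unweighted": metrics(cm, "unweighted").to_dict(),
    }


def boundary_fraction(labels: np.ndarray) -> float:
    """Fraction of labelled pixels 8-adjacent to a differently-labelled pixel.

    A dataset statistic: cut-and-paste pasture scenes have an unusually
    high share of class-boundary pixels, which is why the test loss is an
    unreliable overfitting monitor here.  IGNORE pixels are never counted
    as boundary pixels themselves, but a labelled pixel bordering an
    IGNORE pixel is on a boundary (in composed scenes class transitions
    run through the ignore rims around pasted samples).
    """
    labels = np.asarray(labels)
    valid = labels != IGNORE
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0
    boundary = np.zeros_like(valid)
    h, w = labels.shape
    shifts = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    for dy, dx in shifts:
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        differs = (labels[ys, xs] != labels[ys2, xs2]) & valid[ys, xs]
        boundary[ys, xs] |= differs
    return float(boundary[valid].sum() / n_valid)


def cross_validate(
    sample_pools: dict[str, list],
    k: int,
    build_fold,
    train_and_eval,
    rng: np.random.Generator,
) -> dict:
    """Stratified k-fold cross-validation over named sample pools.

    Each pool is split independently with :func:`sig.stratified_kfold`
    BEFORE any synthetic generation, so no plant sample contributes to two
    folds' synthetic images.  ``build_fold(train_parts, test_parts, fold)``
    must return (train_dataset, test_dataset); ``train_and_eval(train_ds,
    test_ds, fold)`` must return an :class:`EvalReport`.  Per-fold reports
    and their means are returned.
    """
    folds = sig.stratified_kfold(sample_pools, k, rng)
    reports: list[EvalReport] = []
    for i in range(k):
        test_parts = folds[i]
        train_parts = {
            name: [item for j in range(k) if j != i for item in folds[j][name]]
            for name in sample_pools
        }
        train_ds, test_ds = build_fold(train_parts, test_parts, i)
        reports.append(train_and_eval(train_ds, test_ds, i))
    return {
        "per_fold": [r.to_dict() for r in reports],
        "mean_mAcc": float(np.mean([r.mAcc for r in reports])),
        "mean_mIoU": float(np.mean([r.mIoU for r in reports])),
    }


def save_report(report: dict, json_path: str, csv_path: str | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if csv_path and "per_fold" in report:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fold", "mAcc", "mIoU"])
            for i, r in enumerate(report["per_fold"]):
                w.writerow([i, r["mAcc"], r["mIoU"]])
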