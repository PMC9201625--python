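"""Segmentation and classification evaluation metrics.

Confusion-count metrics (Dice, IoU, precision, recall, specificity, F1,
pixel accuracy, accuracy), contour-based Hausdorff distance (exact max and
the HD95 percentile variant), per-case/per-class aggregation, and rank-based
ROC AUC.  All distances are in pixel units; masks are 2-D integer label
images evaluated one-vs-rest per class.

Zero-denominator policy: a ratio whose denominator is empty returns 0.0
(and Dice of two empty masks is defined as 1.0) so that batch aggregation
never produces NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts", "ContourSet", "confusion_counts", "dice",
    "rate_metrics", "extract_contour", "directed_hausdorff", "hausdorff",
    "evaluate_case", "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN tallies."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ContourSet:
    """Set of 2-D contour coordinates (row, col) in pixel units."""

    points: np.ndarray  # (n, 2) ints

    @property
    def is_empty(self) -> bool:
        return self.points.shape[0] == 0


def confusion_counts(pred: np.ndarray, gt: np.ndarray,
                     positive_class: int) -> ConfusionCounts:
    """Tally one-vs-rest confusion counts for ``positive_class``."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred == positive_class
    g = gt == positive_class
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    if den == 0:
        warnings.warn("metric denominator is zero; returning 0.0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    """Dice overlap 2TP / (2TP + FN + FP); two empty masks score 1.0."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0
    return 2.0 * c.tp / (2.0 * c.tp + c.fn + c.fp)


def rate_metrics(c: ConfusionCounts) -> dict[str, float]:
    """All ratio metrics from one confusion tally.

    iou = TP/(TP+FN+FP), pre = TP/(TP+FP), recall = TP/(TP+FN),
    pa = ac = (TP+TN)/total, sp = TN/(TN+FP),
    f1 = 2TP/(2TP+FP+FN) (harmonic mean of precision and recall).
    """
    return {
        "iou": _ratio(c.tp, c.tp + c.fn + c.fp),
        "pre": _ratio(c.tp, c.tp + c.fp),
        "recall": _ratio(c.tp, c.tp + c.fn),
        "f1": _ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn),
        "pa": _ratio(c.tp + c.tn, c.total),
        "ac": _ratio(c.tp + c.tn, c.total),
        "sp": _ratio(c.tn, c.tn + c.fp),
    }


def extract_contour(mask: np.ndarray) -> ContourSet:
    """Foreground pixels with at least one background 4-neighbour.

    Pixels on the image border count as contour (the outside is treated
    as background).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("contour extraction expects a 2-D mask")
    if not mask.any():
        return ContourSet(np.empty((0, 2), dtype=np.intp))
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = binary_erosion(mask, structure=structure, border_value=0)
    return ContourSet(np.argwhere(mask & ~interior))


def _min_dists(a: ContourSet, b: ContourSet) -> np.ndarray:
    tree = cKDTree(b.points)
    d, _ = tree.query(a.points)
    return d


def directed_hausdorff(a: ContourSet, b: ContourSet) -> float:
    """h(A, B) = max over a in A of the min Euclidean distance to B."""
    for side, s in (("A", a), ("B", b)):
        if s.is_empty:
            raise ValueError(f"directed Hausdorff undefined: contour {side} is empty")
    return float(_min_dists(a, b).max())


def hausdorff(a: ContourSet, b: ContourSet,
              percentile: float | None = None) -> float:
    """Symmetric Hausdorff distance max(h(A,B), h(B,A)).

    ``percentile`` (e.g. 95) replaces the max over points with that
    percentile of the directed point distances (the common HD95 variant).
    """
    for side, s in (("A", a), ("B", b)):
        if s.is_empty:
            raise ValueError(f"Hausdorff undefined: contour {side} is empty")
    dab = _min_dists(a, b)
    dba = _min_dists(b, a)
    if percentile is None:
        return float(max(dab.max(), dba.max()))
    return float(max(np.percentile(dab, percentile),
                     np.percentile(dba, percentile)))


def evaluate_case(pred: np.ndarray, gt: np.ndarray,
                  class_ids: list[int] | None = None,
                  percentile: float | None = None) -> dict:
    """Per-class Dice and Hausdorff distance for one prediction/reference pair.

    ``class_ids`` defaults to the foreground labels present in either mask
    (label 0 is background).  Classes absent from both masks score Dice 1.0
    and are excluded from the Hausdorff mean; classes present in exactly one
    mask have an undefined Hausdorff distance (reported as NaN, excluded
    from the mean).  The case summary is the unweighted mean over classes.
    """
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if class_ids is None:
        present = np.union1d(np.unique(pred), np.unique(gt))
        class_ids = [int(c) for c in present if c != 0]

    per_class = {}
    for cid in class_ids:
        c = confusion_counts(pred, gt, cid)
        d = dice(c)
        ca = extract_contour(pred == cid)
        cb = extract_contour(gt == cid)
        if ca.is_empty and cb.is_empty:
            hd = 0.0 if d == 1.0 else float("nan")
        elif ca.is_empty or cb.is_empty:
            hd = float("nan")
        else:
            hd = hausdorff(ca, cb, percentile=percentile)
        with warnings.catch_warnings():
            # absent classes legitimately produce empty denominators here
            warnings.simplefilter("ignore", RuntimeWarning)
            rates = rate_metrics(c)
        per_class[cid] = {"dice": d, "hd": hd, **rates}

    dices = [v["dice"] for v in per_class.values()]
    hds = [v["hd"] for v in per_class.values() if np.isfinite(v["hd"])]
    return {
        "per_class": per_class,
        "mean_dice": float(np.mean(dices)) if dices else 1.0,
        "mean_hd": float(np.mean(hds)) if hds else 0.0,
    }


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Ties are handled by midranks.  ``labels`` must contain both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both positive and negative labels")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))
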