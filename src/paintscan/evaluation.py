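"""Validation metrics for the detector and the baseline scan.

Every x-axis pixel position of every image is treated as an independent
binary test: a pixel is "positive" when it falls inside [x_min, x_max) of
any detection whose score clears the threshold, and the truth labels come
from the (single, full-height) target box, so a default 11-pixel target on
a 200-pixel image contributes 11 positives and 189 negatives.  Confusion
counts are pooled across images before computing precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .painting import BBox

__all__ = [
    "PixelConfusion",
    "EvalReport",
    "pixelwise_confusion",
    "precision_recall",
    "pr_curve_auc",
    "bbox_detection_rate",
    "bbox_summaries",
    "window_heatmap",
    "evaluate_detections",
]


@dataclass
class PixelConfusion:
    """Pixel-level confusion counts pooled over all images."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Pooled performance summary mirroring the study's reporting columns."""

    precision: float
    recall: float
    auc: float | None
    bbox_detection_rate: float | None
    width_mean: float | None
    width_var: float | None
    width_n: int
    count_mean: float
    count_var: float | None
    count_n: int
    precision_defined: bool = True
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "bbox_detection_rate": self.bbox_detection_rate,
            "width_mean": self.width_mean,
            "width_var": self.width_var,
            "width_n": self.width_n,
            "count_mean": self.count_mean,
            "count_var": self.count_var,
            "count_n": self.count_n,
            **self.extras,
        }


def _positive_pixels(boxes, width: int, threshold: float | None = None) -> np.ndarray:
    out = np.zeros(width, dtype=bool)
    for box in boxes:
        if threshold is not None and (box.score is None or not box.score > threshold):
            continue
        out[max(box.x_min, 0) : min(box.x_max, width)] = True
    return out


def pixelwise_confusion(
    detections: list[list[BBox]],
    targets: list[BBox | None],
    width: int,
    threshold: float | None = None,
) -> PixelConfusion:
    """Pool the per-pixel confusion over images.

    ``targets[i]`` may be None for a neutral image (no positive pixels).
    When ``threshold`` is given, only detections with score strictly above
    it count; otherwise all provided boxes count (pre-filtered input).
    """
    conf = PixelConfusion()
    for boxes, target in zip(detections, targets):
        pred = _positive_pixels(boxes, width, threshold)
        truth = target.x_pixels(width) if target is not None else np.zeros(width, dtype=bool)
        conf.tp += int(np.sum(pred & truth))
        conf.fp += int(np.sum(pred & ~truth))
        conf.fn += int(np.sum(~pred & truth))
        conf.tn += int(np.sum(~pred & ~truth))
    return conf


def precision_recall(conf: PixelConfusion) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); an undefined precision (no predicted
    positives) is reported as 0.0 — check ``conf.tp + conf.fp`` if the
    distinction matters."""
    p = conf.tp / (conf.tp + conf.fp) if conf.tp + conf.fp > 0 else 0.0
    r = conf.tp / (conf.tp + conf.fn) if conf.tp + conf.fn > 0 else 0.0
    return p, r


def _pooled_score_arrays(detections, targets, width):
    """Per-pixel best covering score (NaN when uncovered) and truth labels,
    concatenated over images."""
    scores, truth = [], []
    for boxes, target in zip(detections, targets):
        best = np.full(width, np.nan)
        for box in boxes:
            if box.score is None:
                raise ValueError("threshold sweep requires scored detections")
            lo, hi = max(box.x_min, 0), min(box.x_max, width)
            seg = best[lo:hi]
            best[lo:hi] = np.fmax(seg, box.score)
        scores.append(best)
        truth.append(
            target.x_pixels(width) if target is not None else np.zeros(width, dtype=bool)
        )
    return np.concatenate(scores), np.concatenate(truth)


def pr_curve_auc(
    detections: list[list[BBox]],
    targets: list[BBox | None],
    width: int,
    n_thresholds: int = 10_000,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Precision-recall curve over evenly spaced detection thresholds on
    [0, 1], with pixel pooling at each threshold; AUC by the trapezoid rule
    over recall.

    The curve is sorted by recall and extended to recall 0 at its maximum
    observed precision; thresholds with no predicted positives contribute no
    point of their own.  Returns ``(auc, precision, recall)``.
    """
    best, truth = _pooled_score_arrays(detections, targets, width)
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    covered = ~np.isnan(best)
    pos_scores = np.sort(best[covered & truth])
    neg_scores = np.sort(best[covered & ~truth])
    n_truth = int(truth.sum())
    # counts of pixels with score > t, per class, via binary search
    tp = len(pos_scores) - np.searchsorted(pos_scores, thresholds, side="right")
    fp = len(neg_scores) - np.searchsorted(neg_scores, thresholds, side="right")
    predicted = tp + fp
    valid = predicted > 0
    if not np.any(valid) or n_truth == 0:
        return 0.0, np.array([]), np.array([])
    precision = tp[valid] / predicted[valid]
    recall = tp[valid] / n_truth
    order = np.argsort(recall, kind="stable")
    recall_s = recall[order]
    precision_s = precision[order]
    r = np.concatenate(([0.0], recall_s))
    p = np.concatenate(([precision_s.max() if len(precision_s) else 1.0], precision_s))
    auc = float(np.trapezoid(p, r))
    return auc, precision_s, recall_s


def bbox_detection_rate(
    detections: list[list[BBox]], variant_pixels: list[int | None]
) -> tuple[float | None, int]:
    """Fraction of all predicted boxes whose x-range contains the true
    variant pixel; boxes on images without a variant count only in the
    denominator.  Returns ``(rate, n_boxes)`` with rate None when no boxes
    were predicted."""
    hits = 0
    total = 0
    for boxes, pix in zip(detections, variant_pixels):
        total += len(boxes)
        if pix is None:
            continue
        hits += sum(box.contains_x(pix) for box in boxes)
    if total == 0:
        return None, 0
    return hits / total, total


def bbox_summaries(detections: list[list[BBox]]) -> dict:
    """Mean/variance of predicted box widths (over boxes) and of per-image
    box counts (over images, zero-box images included).  Variances use the
    sample convention (n-1 denominator); None when undefined."""
    widths = np.array([box.width for boxes in detections for box in boxes], dtype=float)
    counts = np.array([len(boxes) for boxes in detections], dtype=float)

    def mean_var(x):
        if len(x) == 0:
            return None, None
        return float(x.mean()), (float(x.var(ddof=1)) if len(x) > 1 else None)

    width_mean, width_var = mean_var(widths)
    count_mean = float(counts.mean()) if len(counts) else 0.0
    count_var = float(counts.var(ddof=1)) if len(counts) > 1 else None
    return {
        "width_mean": width_mean,
        "width_var": width_var,
        "width_n": int(len(widths)),
        "count_mean": count_mean,
        "count_var": count_var,
        "count_n": int(len(counts)),
    }


def window_heatmap(classifications: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-window fraction of simulations classified "under selection":
    element-wise mean of equal-length boolean vectors."""
    mat = np.asarray(classifications, dtype=float)
    if mat.ndim != 2:
        raise ValueError("classifications must be a stack of equal-length vectors")
    return mat.mean(axis=0)


def evaluate_detections(
    detections: list[list[BBox]],
    targets: list[BBox | None],
    variant_pixels: list[int | None],
    width: int,
    n_thresholds: int = 10_000,
    compute_auc: bool = True,
) -> EvalReport:
    """One-call summary combining all the study's reporting columns."""
    conf = pixelwise_confusion(detections, targets, width)
    p, r = precision_recall(conf)
    auc = None
    if compute_auc:
        auc, _, _ = pr_curve_auc(detections, targets, width, n_thresholds)
    rate, n_boxes = bbox_detection_rate(detections, variant_pixels)
    summ = bbox_summaries(detections)
    return EvalReport(
        precision=p,
        recall=r,
        auc=auc,
        bbox_detection_rate=rate,
        width_mean=summ["width_mean"],
        width_var=summ["width_var"],
        width_n=summ["width_n"],
        count_mean=summ["count_mean"],
        count_var=summ["count_var"],
        count_n=summ["count_n"],
        precision_defined=conf.tp + conf.fp > 0,
        extras={"confusion": {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn}},
    )
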