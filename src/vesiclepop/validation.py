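"""Object-level validation of a segmentation against a ground-truth mask.

A predicted object matches a true object when the predicted centroid falls
inside the true region and their intersection-over-union is at least the
threshold; each true object can be claimed once (greedy, best IoU first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DetectionScore", "detection_f1"]


@dataclass(frozen=True)
class DetectionScore:
    n_true: int
    n_pred: int
    true_positives: int
    precision: float
    recall: float
    f1: float


def detection_f1(true_labels: np.ndarray, pred_labels: np.ndarray,
                 iou_threshold: float = 0.5) -> DetectionScore:
    """Score predicted labels against true labels at the object level."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    true_ids = [int(i) for i in np.unique(true_labels) if i != 0]
    pred_ids = [int(i) for i in np.unique(pred_labels) if i != 0]
    n_true, n_pred = len(true_ids), len(pred_ids)
    if n_true == 0 or n_pred == 0:
        return DetectionScore(n_true, n_pred, 0, 0.0, 0.0, 0.0)

    true_areas = ndimage.sum_labels(np.ones_like(true_labels), true_labels, true_ids)
    area_by_true = dict(zip(true_ids, true_areas))
    centroids = ndimage.center_of_mass(pred_labels > 0, pred_labels, pred_ids)

    candidates = []  # (iou, pred, true)
    for pid, (cy, cx) in zip(pred_ids, centroids):
        true_at_centroid = int(true_labels[int(round(cy)), int(round(cx))])
        if true_at_centroid == 0:
            continue
        pred_region = pred_labels == pid
        inter = int(np.sum(true_labels[pred_region] == true_at_centroid))
        union = int(pred_region.sum()) + int(area_by_true[true_at_centroid]) - inter
        iou = inter / union if union else 0.0
        if iou >= iou_threshold:
            candidates.append((iou, pid, true_at_centroid))

    candidates.sort(reverse=True)
    used_pred: set[int] = set()
    used_true: set[int] = set()
    tp = 0
    for iou, pid, tid in candidates:
        if pid in used_pred or tid in used_true:
            continue
        used_pred.add(pid)
        used_true.add(tid)
        tp += 1

    precision = tp / n_pred
    recall = tp / n_true
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return DetectionScore(n_true, n_pred, tp, precision, recall, f1)
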