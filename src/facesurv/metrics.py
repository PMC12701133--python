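"""Detection and classification metrics.

Detection follows the COCO-style protocol: greedy confidence-ordered
matching of detections to unmatched ground truth at an IoU threshold,
all-point interpolated precision-recall area for AP, and averaging over an
IoU grid (default 0.50:0.95 step 0.05) and over classes for the summary
numbers.  Classification AUC uses the Mann-Whitney formulation (ties count
one half), which equals trapezoidal ROC integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .types import Box, CLASS_NAMES, Detection, GroundTruthBox

__all__ = [
    "iou", "average_precision", "average_recall", "summarize_detection",
    "classification_metrics", "DetectionMetrics", "ClassificationMetrics",
    "DEFAULT_IOU_THRESHOLDS",
]

DEFAULT_IOU_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two half-open corner boxes."""
    ix = min(box_a.x_max, box_b.x_max) - max(box_a.x_min, box_b.x_min)
    iy = min(box_a.y_max, box_b.y_max) - max(box_a.y_min, box_b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (box_a.area + box_b.area - inter)


@dataclass
class PRArrays:
    precision: np.ndarray
    recall: np.ndarray
    confidence: np.ndarray


@dataclass
class DetectionMetrics:
    ap_per_class: dict[str, float]
    ar_per_class: dict[str, float]
    ap: float                       # class mean, averaged over IoU grid
    ar: float
    map: float                      # alias summary kept for reporting
    precision_at_operating_point: float
    ap50_per_class: dict[str, float]
    pr_curves: dict[str, PRArrays] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "AP": self.ap, "AR": self.ar, "mAP": self.map,
            "precision": self.precision_at_operating_point,
            "AP_per_class": self.ap_per_class,
            "AP50_per_class": self.ap50_per_class,
            "AR_per_class": self.ar_per_class,
        }


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc_fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    pr_precision: np.ndarray = field(default_factory=lambda: np.array([]))
    pr_recall: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "confusion": {"tp": self.tp, "fp": self.fp,
                              "tn": self.tn, "fn": self.fn}}


def average_precision(detections: list[Detection],
                      ground_truth: dict[str, list[GroundTruthBox]],
                      iou_threshold: float) -> tuple[float | None, PRArrays]:
    """All-point interpolated AP for one class at one IoU threshold.

    ``detections`` must share a class; ``ground_truth`` maps image_id to
    that class's GT boxes.  Ties in confidence are broken by input order.
    Returns ``(None, empty)`` when there is neither GT nor detections.
    """
    n_gt = sum(len(v) for v in ground_truth.values())
    empty = PRArrays(np.array([]), np.array([]), np.array([]))
    if n_gt == 0 and not detections:
        return None, empty
    if n_gt == 0:
        return 0.0, empty
    if not detections:
        return 0.0, empty
    order = np.argsort([-d.confidence for d in detections], kind="stable")
    dets = [detections[i] for i in order]
    # greedy matching per image, in global confidence order
    matched: dict[str, np.ndarray] = {
        img: np.zeros(len(g), dtype=bool) for img, g in ground_truth.items()}
    tp = np.zeros(len(dets))
    for i, det in enumerate(dets):
        gts = ground_truth.get(det.image_id, [])
        flags = matched.setdefault(det.image_id, np.zeros(len(gts), dtype=bool))
        best, best_iou = -1, iou_threshold
        for j, gt in enumerate(gts):
            if flags[j]:
                continue
            v = iou(det.box, gt.box)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            flags[best] = True
            tp[i] = 1.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # all-point interpolation: envelope of precision from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        ap += (r - r_prev) * p
        r_prev = r
    conf = np.array([d.confidence for d in dets])
    return float(ap), PRArrays(precision, recall, conf)


def average_recall(detections: list[Detection],
                   ground_truth: dict[str, list[GroundTruthBox]],
                   iou_threshold: float,
                   max_detections: int = 100) -> float | None:
    """Recall at an IoU threshold using up to ``max_detections`` per image."""
    n_gt = sum(len(v) for v in ground_truth.values())
    if n_gt == 0:
        return None
    per_image: dict[str, list[Detection]] = {}
    for d in sorted(detections, key=lambda d: -d.confidence):
        per_image.setdefault(d.image_id, [])
        if len(per_image[d.image_id]) < max_detections:
            per_image[d.image_id].append(d)
    n_matched = 0
    for img, gts in ground_truth.items():
        dets = per_image.get(img, [])
        flags = np.zeros(len(gts), dtype=bool)
        for det in dets:
            best, best_iou = -1, iou_threshold
            for j, gt in enumerate(gts):
                if flags[j]:
                    continue
                v = iou(det.box, gt.box)
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                flags[best] = True
        n_matched += int(flags.sum())
    return n_matched / n_gt


def summarize_detection(detections: list[Detection],
                        ground_truth: dict[str, list[GroundTruthBox]],
                        iou_thresholds=DEFAULT_IOU_THRESHOLDS,
                        operating_score: float = 0.5) -> DetectionMetrics:
    """AP/AR averaged over IoU thresholds and classes.

    ``ground_truth`` maps image_id to all GT boxes of that image; classes
    are split internally.  Classes absent from both GT and detections are
    skipped (flagged by omission from the per-class maps).
    """
    present = [c for c in CLASS_NAMES
               if any(g.class_name == c for gs in ground_truth.values() for g in gs)
               or any(d.class_name == c for d in detections)]
    if not present:
        raise ValueError("no class present in ground truth or detections")
    ap_pc: dict[str, float] = {}
    ar_pc: dict[str, float] = {}
    ap50_pc: dict[str, float] = {}
    curves: dict[str, PRArrays] = {}
    for cname in present:
        gt_c = {img: [g for g in gs if g.class_name == cname]
                for img, gs in ground_truth.items()}
        det_c = [d for d in detections if d.class_name == cname]
        aps = []
        ars = []
        for thr in iou_thresholds:
            ap, pr = average_precision(det_c, gt_c, thr)
            if ap is not None:
                aps.append(ap)
            ar = average_recall(det_c, gt_c, thr)
            if ar is not None:
                ars.append(ar)
            if abs(thr - 0.5) < 1e-9:
                ap50_pc[cname] = ap if ap is not None else np.nan
                curves[cname] = pr
        if aps:
            ap_pc[cname] = float(np.mean(aps))
        if ars:
            ar_pc[cname] = float(np.mean(ars))
    ap_mean = float(np.mean(list(ap_pc.values()))) if ap_pc else np.nan
    ar_mean = float(np.mean(list(ar_pc.values()))) if ar_pc else np.nan
    # precision at the operating score threshold, measured at IoU 0.5
    op_dets = [d for d in detections if d.confidence >= operating_score]
    n_tp = 0
    for cname in present:
        gt_c = {img: [g for g in gs if g.class_name == cname]
                for img, gs in ground_truth.items()}
        det_c = sorted([d for d in op_dets if d.class_name == cname],
                       key=lambda d: -d.confidence)
        matched: dict[str, np.ndarray] = {
            img: np.zeros(len(g), dtype=bool) for img, g in gt_c.items()}
        for det in det_c:
            gts = gt_c.get(det.image_id, [])
            flags = matched.setdefault(det.image_id,
                                       np.zeros(len(gts), dtype=bool))
            for j, gt in enumerate(gts):
                if not flags[j] and iou(det.box, gt.box) >= 0.5:
                    flags[j] = True
                    n_tp += 1
                    break
    op_precision = n_tp / len(op_dets) if op_dets else np.nan
    return DetectionMetrics(
        ap_per_class=ap_pc, ar_per_class=ar_pc, ap=ap_mean, ar=ar_mean,
        map=ap_mean, precision_at_operating_point=float(op_precision),
        ap50_per_class=ap50_pc, pr_curves=curves)


def classification_metrics(labels, scores, threshold: float = 0.5
                           ) -> ClassificationMetrics:
    """Confusion counts at ``threshold`` plus rank-based AUC and curves."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined for single-class labels")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    # Mann-Whitney AUC: mean rank of positives, ties count one half
    ranks = rankdata(s, method="average")
    n_pos = int(y.sum())
    n_neg = n - n_pos
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # ROC / PR arrays over unique thresholds (descending)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    distinct = np.r_[np.where(np.diff(ss) != 0)[0], len(ss) - 1]
    cum_tp = np.cumsum(ys)[distinct]
    cum_fp = np.cumsum(1 - ys)[distinct]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    pr_p = cum_tp / (cum_tp + cum_fp)
    pr_r = cum_tp / n_pos
    return ClassificationMetrics(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        auc=float(auc), tp=tp, fp=fp, tn=tn, fn=fn,
        roc_fpr=fpr, roc_tpr=tpr, pr_precision=pr_p, pr_recall=pr_r)
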