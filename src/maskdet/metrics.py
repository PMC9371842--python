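"""Detection evaluation: accuracy, interpolated AP, size-banded AP.

Matching is the standard greedy protocol: detections sorted by confidence
(ties broken by original index) each claim the not-yet-matched ground truth
with the highest IoU, provided that IoU reaches the threshold.  Average
precision averages the right-running-maximum ("smoothed") precision envelope
over the 101 recall levels 0.00, 0.01, ..., 1.00; precision at unreached
recall counts as zero.

The composite mAP used here is the arithmetic mean of AP50, AP75 and the
three size-banded APs (at IoU 0.5) with half-open area bands
[0, 32^2), [32^2, 96^2), [96^2, inf); the conventional COCO mAP@[.5:.95] is
also provided separately.  Size bands that contain no ground truth are
undefined and are dropped from the composite mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .detection import Detection, iou

__all__ = [
    "MatchedDetections",
    "EvalReport",
    "accuracy",
    "match_detections",
    "pr_points",
    "ap_at",
    "ap_by_size",
    "map_composite",
    "coco_map",
    "evaluate_detections",
]

SMALL_MAX = 32**2
MEDIUM_MAX = 96**2


def accuracy(pred_labels, true_labels) -> float:
    """Fraction of correctly predicted labels."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label lists must have equal length")
    if pred.size == 0:
        raise ValueError("accuracy of an empty sample is undefined")
    return float((pred == true).mean())


@dataclass
class MatchedDetections:
    """Outcome of greedy matching at one IoU threshold, pooled over images."""

    order: np.ndarray        # detection indices sorted by confidence desc
    tp: np.ndarray           # TP flag per detection, in sorted order
    matched_gt: list         # (image_id, gt_index) or None, in sorted order
    n_gt: int
    scores: np.ndarray       # confidence per detection, in sorted order


def _det_list(dets) -> list[tuple[int, np.ndarray, float, int]]:
    """Normalize per-image detections to (image_id, box, score, class)."""
    flat = []
    for img_id, per_img in enumerate(dets):
        for d in per_img:
            if isinstance(d, Detection):
                flat.append((img_id, np.asarray(d.box, float), d.score,
                             d.class_id))
            else:
                box, score, cls = d
                flat.append((img_id, np.asarray(box, float), float(score),
                             int(cls)))
    return flat


def _gt_list(gts) -> list[tuple[int, np.ndarray, int]]:
    flat = []
    for img_id, per_img in enumerate(gts):
        boxes, labels = per_img
        for box, lab in zip(np.asarray(boxes, float).reshape(-1, 4),
                            np.asarray(labels).reshape(-1)):
            flat.append((img_id, box, int(lab)))
    return flat


def match_detections(dets, gts, iou_thr: float,
                     class_aware: bool = True) -> MatchedDetections:
    """Greedy confidence-descending matching, each gt claimed at most once.

    ``dets``: per image, a list of Detection (or (box, score, class) tuples);
    ``gts``: per image, a pair (boxes, labels).
    """
    if not (0.0 < iou_thr < 1.0):
        raise ValueError("iou_thr must lie in (0,1)")
    flat_d = _det_list(dets)
    flat_g = _gt_list(gts)
    order = sorted(range(len(flat_d)),
                   key=lambda i: (-flat_d[i][2], i))
    used: set[int] = set()
    tp = np.zeros(len(order), dtype=bool)
    matched: list = [None] * len(order)
    for rank, di in enumerate(order):
        img_id, box, _, cls = flat_d[di]
        best_iou, best_g = 0.0, None
        for gi, (g_img, g_box, g_lab) in enumerate(flat_g):
            if g_img != img_id or gi in used:
                continue
            if class_aware and g_lab != cls:
                continue
            v = iou(box, g_box)
            if v >= iou_thr and v > best_iou:
                best_iou, best_g = v, gi
        if best_g is not None:
            used.add(best_g)
            tp[rank] = True
            matched[rank] = (img_id, best_g)
    scores = np.array([flat_d[i][2] for i in order])
    return MatchedDetections(np.array(order, dtype=int), tp, matched,
                             len(flat_g), scores)


def pr_points(dets, gts, iou_thr: float):
    """Cumulative precision/recall plus the right-running-max envelope.

    Returns (precision, recall, envelope) arrays, one entry per detection in
    confidence order; all empty when there are neither detections nor gts.
    """
    m = match_detections(dets, gts, iou_thr)
    if len(m.tp) == 0:
        return np.array([]), np.array([]), np.array([])
    tp_cum = np.cumsum(m.tp)
    fp_cum = np.cumsum(~m.tp)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / m.n_gt if m.n_gt > 0 else np.zeros_like(precision)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    return precision, recall, envelope


def _ap_from_pr(recall: np.ndarray, envelope: np.ndarray) -> float:
    """Mean envelope precision over the 101-point recall grid 0.00..1.00."""
    if len(recall) == 0:
        return 0.0
    grid = np.linspace(0.0, 1.0, 101)
    # envelope precision at the first point with recall >= r, else 0
    idx = np.searchsorted(recall, grid, side="left")
    prec = np.where(idx < len(recall), envelope[np.minimum(idx, len(recall) - 1)],
                    0.0)
    return float(prec.mean())


def ap_at(dets, gts, iou_thr: float) -> float:
    """101-point interpolated average precision at one IoU threshold."""
    _, recall, envelope = pr_points(dets, gts, iou_thr)
    return _ap_from_pr(recall, envelope)


def _area(box) -> float:
    return float((box[2] - box[0]) * (box[3] - box[1]))


def _band_of(area: float) -> str:
    if area < SMALL_MAX:
        return "small"
    if area < MEDIUM_MAX:
        return "medium"
    return "large"


def ap_by_size(dets, gts, iou_thr: float = 0.5):
    """(ap_small, ap_medium, ap_large); a band with no gt is None.

    Matching runs once on the full scene; for each band the ground truths
    are restricted to the band and detections matched to out-of-band ground
    truths are discarded (unmatched detections stay and count as false
    positives against every band).
    """
    m = match_detections(dets, gts, iou_thr)
    flat_g = _gt_list(gts)
    g_band = [_band_of(_area(box)) for _, box, _ in flat_g]
    results = {}
    for band in ("small", "medium", "large"):
        n_gt_band = sum(1 for b in g_band if b == band)
        if n_gt_band == 0:
            results[band] = None
            continue
        tp_flags, scores = [], []
        for rank in range(len(m.tp)):
            if m.tp[rank]:
                gi = m.matched_gt[rank][1]
                if g_band[gi] != band:
                    continue  # matched to another band: ignored, not FP
                tp_flags.append(True)
            else:
                tp_flags.append(False)
            scores.append(m.scores[rank])
        if not tp_flags:
            results[band] = 0.0
            continue
        tp = np.array(tp_flags)
        tp_cum = np.cumsum(tp)
        fp_cum = np.cumsum(~tp)
        precision = tp_cum / (tp_cum + fp_cum)
        recall = tp_cum / n_gt_band
        envelope = np.maximum.accumulate(precision[::-1])[::-1]
        results[band] = _ap_from_pr(recall, envelope)
    return results["small"], results["medium"], results["large"]


def map_composite(ap50: float | None, ap75: float | None,
                  ap_s: float | None, ap_m: float | None,
                  ap_l: float | None) -> float:
    """Mean of the defined components among {AP50, AP75, AP_S, AP_M, AP_L}."""
    defined = [v for v in (ap50, ap75, ap_s, ap_m, ap_l) if v is not None]
    if not defined:
        raise ValueError("all composite-mAP components are undefined")
    if len(defined) < 5:
        warnings.warn(
            "composite mAP averaged over %d of 5 components (empty size bands"
            " dropped)" % len(defined), stacklevel=2,
        )
    return float(np.mean(defined))


def coco_map(dets, gts) -> float:
    """Conventional COCO mAP: mean AP over IoU thresholds 0.50:0.05:0.95."""
    thrs = np.arange(0.5, 0.96, 0.05)
    return float(np.mean([ap_at(dets, gts, float(t)) for t in thrs]))


@dataclass
class EvalReport:
    """Detection-run summary: classification accuracy, AP components,
    the composite mAP, and the standard COCO mAP for reference."""

    accuracy: float
    ap50: float
    ap75: float
    ap_s: float | None
    ap_m: float | None
    ap_l: float | None
    map_composite: float
    coco_map: float
    n_images: int
    n_gt: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "accuracy", "ap50", "ap75", "ap_s", "ap_m", "ap_l",
            "map_composite", "coco_map", "n_images", "n_gt")}


def evaluate_detections(dets, gts) -> EvalReport:
    """Full evaluation of per-image detections against per-image gts.

    Classification accuracy is per ground truth: a gt counts as correctly
    classified when greedy class-agnostic matching at IoU 0.5 pairs it with
    a detection of its own class; unmatched gts count as errors.
    """
    m = match_detections(dets, gts, 0.5, class_aware=False)
    flat_d = _det_list(dets)
    flat_g = _gt_list(gts)
    pred_labels = np.full(len(flat_g), -1, dtype=int)
    for rank, di in enumerate(m.order):
        if m.tp[rank]:
            gi = m.matched_gt[rank][1]
            pred_labels[gi] = flat_d[di][3]
    true_labels = np.array([g[2] for g in flat_g], dtype=int)
    acc = accuracy(pred_labels, true_labels) if len(flat_g) else 0.0
    ap50 = ap_at(dets, gts, 0.5)
    ap75 = ap_at(dets, gts, 0.75)
    ap_s, ap_m, ap_l = ap_by_size(dets, gts, 0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = map_composite(ap50, ap75, ap_s, ap_m, ap_l)
    return EvalReport(
        accuracy=acc, ap50=ap50, ap75=ap75, ap_s=ap_s, ap_m=ap_m, ap_l=ap_l,
        map_composite=comp, coco_map=coco_map(dets, gts),
        n_images=len(dets), n_gt=len(flat_g),
    )
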