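"""Decoding, non-maximum suppression and the detection evaluation suite.

Covers per-class precision/recall, all-point and 101-point interpolated
average precision, mAP@.5 and mAP@.5:.95, the Matthews correlation
coefficient and a threshold-swept ROC curve.

Detection lacks true negatives, so MCC and the ROC false-positive rate use a
detection-adapted TN: the model's decision space is the finite set of
anchor-cells over all scales, and TN counts the anchor-cells that are
neither responsible for any ground-truth box nor produce a detection above
threshold.  With that convention both quantities are well defined and
micro-averaged over classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boxes import BBox, iou
from .detector import DetectorConfig
from .losses import decode_grid


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_id: int
    score: float
    box: BBox

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")


@dataclass
class MatchResult:
    """Per-class matching outcome: score-ordered TP/FP flags and counts."""

    tp: int
    fp: int
    fn: int
    flags: list[bool]          # score-descending; True = TP
    scores: list[float]
    n_gt: int


@dataclass
class EvalReport:
    per_class_precision: dict[int, float]
    per_class_recall: dict[int, float]
    per_class_ap: dict[int, float]
    map50: float
    map50_95: float
    mcc: float
    roc_points: list[tuple[float, float, float]]  # (threshold, FPR, TPR)
    auc: float
    roc_degenerate: bool = False


def anchor_cell_count(config: DetectorConfig, n_images: int) -> int:
    """Size of the detector's decision space: anchor-cells over all scales."""
    return n_images * sum(3 * gh * gw for gh, gw in config.grid_sizes())


def decode_predictions(pred_grids: list[np.ndarray], config: DetectorConfig,
                       score_thresh: float = 0.25,
                       image_ids: list[str] | None = None) -> list[Detection]:
    """Decode raw grids for a batch into thresholded detections.

    Score = objectness * max class probability; boxes are clipped to the
    frame and emitted in normalized coordinates.
    """
    n = pred_grids[0].shape[0]
    if image_ids is None:
        image_ids = [str(i) for i in range(n)]
    dets: list[Detection] = []
    for s, pred in enumerate(pred_grids):
        xy, wh, conf, cls_prob = decode_grid(pred, s, config)
        score = conf[..., None] * cls_prob
        best_cls = score.argmax(axis=-1)
        best_score = score.max(axis=-1)
        keep = np.argwhere(best_score >= score_thresh)
        for (ni, a, r, c) in keep:
            bx, by = xy[ni, a, r, c]
            bw, bh = wh[ni, a, r, c]
            x1, y1 = max(0.0, bx - bw / 2), max(0.0, by - bh / 2)
            x2, y2 = min(1.0, bx + bw / 2), min(1.0, by + bh / 2)
            if x2 - x1 <= 1e-6 or y2 - y1 <= 1e-6:
                continue
            dets.append(Detection(
                image_id=image_ids[ni],
                class_id=int(best_cls[ni, a, r, c]),
                score=float(min(1.0, best_score[ni, a, r, c])),
                box=BBox.from_corners(int(best_cls[ni, a, r, c]), x1, y1, x2, y2),
            ))
    return dets


def _det_sort_key(d: Detection):
    return (-d.score, d.box.cx, d.box.cy, d.box.w, d.box.h, d.class_id)


def nms(dets: list[Detection], iou_thresh: float = 0.45) -> list[Detection]:
    """Greedy class-wise suppression; output sorted by descending score.

    Input-order independent: ties in score are broken by box coordinates.
    """
    kept: list[Detection] = []
    for d in sorted(dets, key=_det_sort_key):
        if all(k.class_id != d.class_id or iou(k.box, d.box) < iou_thresh
               for k in kept):
            kept.append(d)
    return kept


def match_detections(dets: list[Detection], gts: dict[str, list[BBox]],
                     iou_thresh: float = 0.5) -> dict[int, MatchResult]:
    """Greedy highest-score-first one-to-one matching per class.

    ``gts`` maps image_id -> ground-truth boxes.  Returns per-class results;
    classes present in either detections or GT are reported.
    """
    classes = {d.class_id for d in dets}
    for boxes in gts.values():
        classes |= {b.class_id for b in boxes}
    out: dict[int, MatchResult] = {}
    for c in sorted(classes):
        cdets = sorted([d for d in dets if d.class_id == c], key=_det_sort_key)
        gt_pool = {
            img: [b for b in boxes if b.class_id == c]
            for img, boxes in gts.items()
        }
        n_gt = sum(len(v) for v in gt_pool.values())
        used: dict[str, set[int]] = {img: set() for img in gt_pool}
        flags: list[bool] = []
        for d in cdets:
            cand = gt_pool.get(d.image_id, [])
            best_i, best_iou = -1, iou_thresh
            for i, g in enumerate(cand):
                if i in used.get(d.image_id, set()):
                    continue
                v = iou(d.box, g)
                if v >= best_iou:
                    best_iou, best_i = v, i
            if best_i >= 0:
                used.setdefault(d.image_id, set()).add(best_i)
                flags.append(True)
            else:
                flags.append(False)
        tp = sum(flags)
        out[c] = MatchResult(tp=tp, fp=len(flags) - tp, fn=n_gt - tp,
                             flags=flags, scores=[d.score for d in cdets],
                             n_gt=n_gt)
    return out


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty denominators default to
    precision 0 (no detections) and recall 1 (no ground truth)."""
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 1.0
    return p, r


def average_precision(flags: list[bool], n_gt: int,
                      mode: str = "all_point") -> float | None:
    """AP from score-ordered TP/FP flags.

    ``all_point``: exact area under the interpolated (max-to-the-right)
    precision-recall curve.  ``coco101``: mean interpolated precision at 101
    evenly spaced recall points.  ``n_gt`` = 0 -> None (excluded from means).
    """
    if n_gt == 0:
        return None
    if not flags:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: best precision at any recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if mode == "all_point":
        ap = 0.0
        prev_r = 0.0
        for r, p, f in zip(recall, env, flags):
            if f:
                ap += (r - prev_r) * p
                prev_r = r
        return float(ap)
    if mode == "coco101":
        pts = np.linspace(0.0, 1.0, 101)
        interp = np.zeros_like(pts)
        for i, r in enumerate(pts):
            mask = recall >= r - 1e-12
            interp[i] = env[mask][0] if mask.any() else 0.0
        return float(interp.mean())
    raise ValueError(f"unknown AP mode {mode!r}")


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; zero denominator -> 0."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def roc_curve(dets: list[Detection], gts: dict[str, list[BBox]],
              total_cells: int, iou_thresh: float = 0.5,
              thresholds: np.ndarray | None = None):
    """Sweep score thresholds (default 0.1 to 1.0 in steps of 0.1) and
    report (threshold, FPR, TPR) points plus trapezoidal AUC with the
    endpoints (0,0) and (1,1) appended.

    ``total_cells`` is the anchor-cell decision-space size used for the
    detection-adapted TN.  A detector that never fires yields a degenerate
    all-zero TPR curve; it is still integrated (AUC 0.5 from the endpoints)
    and flagged.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.1, 1.01, 0.1), 10)
    points = []
    any_tp = False
    for t in thresholds:
        kept = [d for d in dets if d.score >= t]
        res = match_detections(kept, gts, iou_thresh)
        tp = sum(m.tp for m in res.values())
        fp = sum(m.fp for m in res.values())
        fn = sum(m.fn for m in res.values())
        tn = max(0, total_cells - tp - fp - fn)
        tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
        any_tp = any_tp or tp > 0
        points.append((float(t), fpr, tpr))
    pts = sorted([(p[1], p[2]) for p in points]) + [(1.0, 1.0)]
    pts = [(0.0, 0.0)] + pts
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc), (not any_tp)


def map_suite(dets: list[Detection], gts: dict[str, list[BBox]],
              n_classes: int, score_thresh: float = 0.25,
              total_cells: int | None = None) -> EvalReport:
    """Full evaluation: per-class P/R/AP, mAP@.5 (all-point AP),
    mAP@.5:.95 (101-point AP averaged over IoU 0.50:0.05:0.95),
    micro-averaged MCC at the score threshold, and the ROC sweep."""
    if total_cells is None:
        # reasonable default decision space if no detector config is known:
        # one 40x40 + 20x20 + 10x10 three-anchor grid per image
        total_cells = max(1, len(gts)) * 3 * (1600 + 400 + 100)

    m50 = match_detections(dets, gts, 0.5)
    per_p, per_r, per_ap = {}, {}, {}
    ap_values = []
    for c, m in m50.items():
        thresh_m = match_detections(
            [d for d in dets if d.score >= score_thresh and d.class_id == c],
            {img: [b for b in boxes if b.class_id == c]
             for img, boxes in gts.items()}, 0.5)
        mt = thresh_m.get(c, MatchResult(0, 0, m.n_gt, [], [], m.n_gt))
        per_p[c], per_r[c] = precision_recall(mt)
        ap = average_precision(m.flags, m.n_gt, "all_point")
        if ap is not None:
            per_ap[c] = ap
            ap_values.append(ap)
    map50 = float(np.mean(ap_values)) if ap_values else 0.0

    iou_grid = np.round(np.arange(0.5, 0.96, 0.05), 10)
    ap_all = []
    for t in iou_grid:
        mt = match_detections(dets, gts, float(t))
        for c, m in mt.items():
            ap = average_precision(m.flags, m.n_gt, "coco101")
            if ap is not None:
                ap_all.append(ap)
    map5095 = float(np.mean(ap_all)) if ap_all else 0.0

    kept = [d for d in dets if d.score >= score_thresh]
    mres = match_detections(kept, gts, 0.5)
    tp = sum(m.tp for m in mres.values())
    fp = sum(m.fp for m in mres.values())
    fn = sum(m.fn for m in mres.values())
    tn = max(0, total_cells - tp - fp - fn)
    mcc_val = mcc(tp, tn, fp, fn)

    roc_pts, auc, degenerate = roc_curve(dets, gts, total_cells)
    return EvalReport(
        per_class_precision=per_p, per_class_recall=per_r, per_class_ap=per_ap,
        map50=map50, map50_95=map5095, mcc=mcc_val,
        roc_points=roc_pts, auc=auc, roc_degenerate=degenerate,
    )
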