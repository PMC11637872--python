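"""Target assignment and the three-part detection training loss.

The loss over a prediction grid has an object (box-regression) term, a class
term and a confidence term::

    l_obj  = sum_obj [(x - x^)^2 + (y - y^)^2] + sum_obj [(w - w^)^2 + (h - h^)^2]
    l_cls  = sum_obj sum_c (p(c) - p^(c))^2
    l_conf = sum_obj (C - C^)^2 + lambda_noobj * sum_noobj (C - C^)^2
    total  = alpha * l_obj + beta * l_cls + gamma * l_conf

with plain squared differences on w and h (a square-root variant and a
1-CIoU box term are selectable).  The confidence target C of a responsible
anchor-cell is the IoU between the decoded predicted box and its ground
truth; no-object cells have C = 0.  The IoU target is treated as a constant
in the analytic gradient, the usual convention for this loss family.

Raw predictions decode as: x^ = (col + sigmoid(t_x)) / S (cell-relative,
normalized), likewise y^, and w^ = (2 sigmoid(t_w))^2 * anchor_w / W
(anchor-scaled, exponential-free), likewise h^.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BBox, ciou, ciou_corners, iou, iou_corners  # noqa: F401  (re-exported geometry)
from .detector import DetectorConfig


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.05   # box term
    beta: float = 0.5     # class term
    gamma: float = 1.0    # confidence term
    lambda_noobj: float = 0.5

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.lambda_noobj) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    l_obj: float
    l_cls: float
    l_conf: float
    total: float

    def __post_init__(self) -> None:
        if min(self.l_obj, self.l_cls, self.l_conf) < -1e-9:
            raise ValueError("loss components must be non-negative")


@dataclass
class AssignmentMask:
    """Per-scale responsibility masks and matched targets for one image.

    For scale index s: ``obj[s]`` is a boolean (3, Sh, Sw) indicator;
    ``txywh[s]`` holds the matched normalized GT box at responsible cells;
    ``cls[s]`` the matched class id (-1 elsewhere).  The no-object set is the
    complement of ``obj``.
    """

    obj: list[np.ndarray]
    txywh: list[np.ndarray]
    cls: list[np.ndarray]

    def n_responsible(self) -> int:
        return int(sum(m.sum() for m in self.obj))


def assign_targets(gt: list[BBox], config: DetectorConfig,
                   ratio_thresh: float = 4.0) -> AssignmentMask:
    """Assign each GT box to the grid cell containing its center at every
    scale whose anchor matches by the size-ratio rule
    ``max(w/wa, wa/w, h/ha, ha/h) < ratio_thresh``; a GT that matches no
    anchor falls back to the overall best-ratio anchor, so every box ends up
    with at least one responsible anchor-cell.
    """
    H, W = config.input_size
    anchors = config.anchors_array()
    grids = config.grid_sizes()
    obj = [np.zeros((3, gh, gw), dtype=bool) for gh, gw in grids]
    txywh = [np.zeros((3, gh, gw, 4), dtype=np.float64) for gh, gw in grids]
    cls = [np.full((3, gh, gw), -1, dtype=np.int64) for gh, gw in grids]

    for box in gt:
        bw_px, bh_px = box.w * W, box.h * H
        ratios = np.maximum.reduce([
            bw_px / anchors[..., 0], anchors[..., 0] / bw_px,
            bh_px / anchors[..., 1], anchors[..., 1] / bh_px,
        ])  # (3 scales, 3 anchors)
        placed = False
        for s, (gh, gw) in enumerate(grids):
            row = min(int(box.cy * gh), gh - 1)
            col = min(int(box.cx * gw), gw - 1)
            for a in range(3):
                if ratios[s, a] < ratio_thresh and not obj[s][a, row, col]:
                    obj[s][a, row, col] = True
                    txywh[s][a, row, col] = (box.cx, box.cy, box.w, box.h)
                    cls[s][a, row, col] = box.class_id
                    placed = True
        if not placed:
            # best-ratio fallback, first unoccupied in ratio order
            flat = np.argsort(ratios, axis=None)
            for f in flat:
                s, a = divmod(int(f), 3)
                gh, gw = grids[s]
                row = min(int(box.cy * gh), gh - 1)
                col = min(int(box.cx * gw), gw - 1)
                if not obj[s][a, row, col]:
                    obj[s][a, row, col] = True
                    txywh[s][a, row, col] = (box.cx, box.cy, box.w, box.h)
                    cls[s][a, row, col] = box.class_id
                    placed = True
                    break
            if not placed:  # every candidate occupied: overwrite the best
                s, a = divmod(int(flat[0]), 3)
                gh, gw = grids[s]
                row = min(int(box.cy * gh), gh - 1)
                col = min(int(box.cx * gw), gw - 1)
                txywh[s][a, row, col] = (box.cx, box.cy, box.w, box.h)
                cls[s][a, row, col] = box.class_id
    return AssignmentMask(obj=obj, txywh=txywh, cls=cls)


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def decode_grid(pred: np.ndarray, scale_idx: int, config: DetectorConfig):
    """Decode one raw scale grid (N, 3, Sh, Sw, 5+nc) to normalized boxes.

    Returns (xy, wh, conf, cls_prob): xy/wh (N,3,Sh,Sw,2) normalized box
    center/extent, conf (N,3,Sh,Sw) objectness probability, cls_prob
    (N,3,Sh,Sw,nc) per-class sigmoid probabilities.
    """
    H, W = config.input_size
    gh, gw = config.grid_sizes()[scale_idx]
    anchors = config.anchors_array()[scale_idx]  # (3, 2) px
    sx = _sigmoid(pred[..., 0])
    sy = _sigmoid(pred[..., 1])
    sw = _sigmoid(pred[..., 2])
    sh = _sigmoid(pred[..., 3])
    cols = np.arange(gw)[None, None, None, :]
    rows = np.arange(gh)[None, None, :, None]
    x = (cols + sx) / gw
    y = (rows + sy) / gh
    w = (2.0 * sw) ** 2 * (anchors[None, :, None, None, 0] / W)
    h = (2.0 * sh) ** 2 * (anchors[None, :, None, None, 1] / H)
    conf = _sigmoid(pred[..., 4])
    cls_prob = _sigmoid(pred[..., 5:])
    return np.stack([x, y], axis=-1), np.stack([w, h], axis=-1), conf, cls_prob


def _iou_xywh_arrays(a_xy, a_wh, b_xy, b_wh):
    """Vectorized IoU of center-format boxes (broadcastable arrays)."""
    ax1, ay1 = a_xy[..., 0] - a_wh[..., 0] / 2, a_xy[..., 1] - a_wh[..., 1] / 2
    ax2, ay2 = a_xy[..., 0] + a_wh[..., 0] / 2, a_xy[..., 1] + a_wh[..., 1] / 2
    bx1, by1 = b_xy[..., 0] - b_wh[..., 0] / 2, b_xy[..., 1] - b_wh[..., 1] / 2
    bx2, by2 = b_xy[..., 0] + b_wh[..., 0] / 2, b_xy[..., 1] + b_wh[..., 1] / 2
    iw = np.maximum(0.0, np.minimum(ax2, bx2) - np.maximum(ax1, bx1))
    ih = np.maximum(0.0, np.minimum(ay2, by2) - np.maximum(ay1, by1))
    inter = iw * ih
    union = a_wh[..., 0] * a_wh[..., 1] + b_wh[..., 0] * b_wh[..., 1] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def confidence_targets(pred_grids: list[np.ndarray],
                       masks: list[AssignmentMask],
                       config: DetectorConfig) -> list[np.ndarray]:
    """Per-scale confidence targets: IoU(decoded pred box, matched GT box)
    at responsible anchor-cells, 0 elsewhere."""
    out = []
    for s, pred in enumerate(pred_grids):
        xy, wh, _, _ = decode_grid(pred, s, config)
        obj = np.stack([m.obj[s] for m in masks])
        gt = np.stack([m.txywh[s] for m in masks])
        ious = _iou_xywh_arrays(xy, wh, gt[..., :2], gt[..., 2:])
        out.append(np.where(obj, ious, 0.0))
    return out


def detection_loss(pred_grids: list[np.ndarray],
                   masks: list[AssignmentMask],
                   weights: LossWeights,
                   config: DetectorConfig,
                   conf_targets: list[np.ndarray] | None = None,
                   box_loss: str = "sse",
                   compute_grad: bool = False):
    """Evaluate the three-part loss over a batch of raw prediction grids.

    ``pred_grids``: per scale, (N, 3, Sh, Sw, 5+nc) raw head outputs;
    ``masks``: one AssignmentMask per image.  Losses are *sums* over the
    batch, so the batch loss equals the sum of per-image losses.

    ``box_loss``: "sse" (squared differences as printed), "sqrt"
    (square-root w/h variant) or "ciou" (1 - CIoU).

    Returns ``LossBreakdown`` or ``(LossBreakdown, grads)`` with per-scale
    gradient arrays w.r.t. the raw predictions when ``compute_grad``.
    """
    for s, pred in enumerate(pred_grids):
        if not np.all(np.isfinite(pred)):
            bad = np.argwhere(~np.isfinite(pred))[0]
            raise FloatingPointError(
                f"non-finite prediction at scale {s}, index {tuple(bad)}"
            )
    if conf_targets is None:
        conf_targets = confidence_targets(pred_grids, masks, config)

    H, W = config.input_size
    nc = config.n_classes
    l_obj = l_cls = l_conf = 0.0
    grads = [np.zeros_like(p) for p in pred_grids] if compute_grad else None

    for s, pred in enumerate(pred_grids):
        gh, gw = config.grid_sizes()[s]
        anchors = config.anchors_array()[s]
        xy, wh, conf, cls_prob = decode_grid(pred, s, config)
        obj = np.stack([m.obj[s] for m in masks])          # (N,3,gh,gw)
        gt = np.stack([m.txywh[s] for m in masks])          # (N,3,gh,gw,4)
        gcls = np.stack([m.cls[s] for m in masks])          # (N,3,gh,gw)
        noobj = ~obj
        ct = conf_targets[s]

        # confidence term (both obj and noobj cells)
        dconf = conf - ct
        l_conf += float((dconf[obj] ** 2).sum()
                        + weights.lambda_noobj * (dconf[noobj] ** 2).sum())

        if compute_grad:
            w_conf = np.where(obj, 1.0, weights.lambda_noobj)
            grads[s][..., 4] += (weights.gamma * 2.0 * w_conf * dconf
                                 * conf * (1.0 - conf))

        if not obj.any():
            continue

        # class term
        oc = gcls[obj]
        onehot_obj = np.zeros((oc.shape[0], nc))
        onehot_obj[np.arange(oc.shape[0]), oc] = 1.0
        dcls = cls_prob[obj] - onehot_obj
        l_cls += float((dcls ** 2).sum())

        # box term on decoded coordinates
        dxy = xy[obj] - gt[obj][:, :2]
        dwh = wh[obj] - gt[obj][:, 2:]
        if box_loss == "sse":
            l_obj += float((dxy ** 2).sum() + (dwh ** 2).sum())
        elif box_loss == "sqrt":
            dswh = np.sqrt(wh[obj]) - np.sqrt(gt[obj][:, 2:])
            l_obj += float((dxy ** 2).sum() + (dswh ** 2).sum())
        elif box_loss == "ciou":
            for pxy, pwh, txy_, twh_ in zip(xy[obj], wh[obj],
                                            gt[obj][:, :2], gt[obj][:, 2:]):
                pa = (pxy[0] - pwh[0] / 2, pxy[1] - pwh[1] / 2,
                      pxy[0] + pwh[0] / 2, pxy[1] + pwh[1] / 2)
                ta = (txy_[0] - twh_[0] / 2, txy_[1] - twh_[1] / 2,
                      txy_[0] + twh_[0] / 2, txy_[1] + twh_[1] / 2)
                l_obj += 1.0 - ciou_corners(ta, pa)
        else:
            raise ValueError(f"unknown box_loss mode {box_loss!r}")

        if compute_grad:
            if box_loss == "ciou":
                raise NotImplementedError(
                    "analytic gradients are provided for the sse/sqrt box terms"
                )
            sx = _sigmoid(pred[..., 0])[obj]
            sy = _sigmoid(pred[..., 1])[obj]
            sw = _sigmoid(pred[..., 2])[obj]
            sh = _sigmoid(pred[..., 3])[obj]
            # d x^ / d t_x = sigmoid'(t_x) / gw  etc.
            gx = weights.alpha * 2.0 * dxy[:, 0] * sx * (1 - sx) / gw
            gy = weights.alpha * 2.0 * dxy[:, 1] * sy * (1 - sy) / gh
            # w^ = (2 sw)^2 * aw  ->  d w^ / d t_w = 8 sw sw' aw
            aw = np.take(anchors[:, 0] / W, np.argwhere(obj)[:, 1])
            ah = np.take(anchors[:, 1] / H, np.argwhere(obj)[:, 1])
            if box_loss == "sse":
                dw_term, dh_term = dwh[:, 0], dwh[:, 1]
            else:  # sqrt
                dw_term = (np.sqrt(wh[obj][:, 0]) - np.sqrt(gt[obj][:, 2])) \
                    / (2.0 * np.sqrt(np.maximum(wh[obj][:, 0], 1e-12)))
                dh_term = (np.sqrt(wh[obj][:, 1]) - np.sqrt(gt[obj][:, 3])) \
                    / (2.0 * np.sqrt(np.maximum(wh[obj][:, 1], 1e-12)))
            gw_ = weights.alpha * 2.0 * dw_term * 8.0 * sw * sw * (1 - sw) * aw
            gh_ = weights.alpha * 2.0 * dh_term * 8.0 * sh * sh * (1 - sh) * ah
            gcls_grad = (weights.beta * 2.0 * dcls
                         * cls_prob[obj] * (1.0 - cls_prob[obj]))
            idx = np.argwhere(obj)
            sel = (idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3])
            grads[s][sel + (0,)] += gx
            grads[s][sel + (1,)] += gy
            grads[s][sel + (2,)] += gw_
            grads[s][sel + (3,)] += gh_
            grads[s][(*sel, slice(5, None))] += gcls_grad

    total = (weights.alpha * l_obj + weights.beta * l_cls
             + weights.gamma * l_conf)
    breakdown = LossBreakdown(l_obj=l_obj, l_cls=l_cls, l_conf=l_conf,
                              total=total)
    if compute_grad:
        return breakdown, grads
    return breakdown
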