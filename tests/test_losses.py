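"""Target assignment and the three-part loss: hand oracles and gradients."""

import numpy as np
import pytest

from chmmi.detector import DetectorConfig
from chmmi.boxes import BBox
from chmmi.losses import (LossBreakdown, LossWeights, assign_targets,
                          confidence_targets, decode_grid, detection_loss)


def _logit(p):
    return float(np.log(p / (1.0 - p)))


def _zero_grids(cfg, n=1, conf_raw=-40.0):
    """Raw grids with objectness pinned far negative (sigmoid ~ 0)."""
    grids = []
    for gh, gw in cfg.grid_sizes():
        g = np.zeros((n, 3, gh, gw, 5 + cfg.n_classes))
        g[..., 4] = conf_raw
        grids.append(g)
    return grids


@pytest.fixture(scope="module")
def cfg64():
    return DetectorConfig(n_classes=2, input_size=(64, 64),
                          widths=(4, 6, 8, 10, 12), seed=0)


class TestAssignTargets:
    def test_center_cell_at_stride_8(self):
        cfg = DetectorConfig(n_classes=9, input_size=(320, 320))
        mask = assign_targets([BBox(0, 0.5, 0.5, 0.0625, 0.0625)], cfg)
        rows = np.argwhere(mask.obj[0])
        assert len(rows) >= 1
        assert all((r, c) == (20, 20) for _, r, c in rows)

    def test_no_boxes_all_noobj(self, cfg64):
        mask = assign_targets([], cfg64)
        assert mask.n_responsible() == 0

    def test_every_box_gets_a_cell(self, cfg64, rng):
        for _ in range(50):
            cx, cy = rng.uniform(0.05, 0.95, 2)
            w, h = rng.uniform(0.01, 0.9, 2)
            try:
                boxes = [BBox(0, cx, cy, w, h)]
            except ValueError:
                continue
            mask = assign_targets(boxes, cfg64)
            assert mask.n_responsible() >= 1

    def test_obj_and_noobj_partition(self, cfg64):
        mask = assign_targets([BBox(1, 0.3, 0.3, 0.2, 0.2)], cfg64)
        total = sum(m.size for m in mask.obj)
        n_obj = mask.n_responsible()
        n_noobj = sum((~m).sum() for m in mask.obj)
        assert n_obj + n_noobj == total


class TestDetectionLossOracles:
    def test_perfect_predictions_zero_loss(self, cfg64):
        """Raw preds encoding the GT box exactly, confidence = IoU = 1 at the
        responsible cells and ~0 elsewhere, give all components ~0."""
        gt = [BBox(1, 0.39, 0.61, 0.25, 0.22)]
        mask = assign_targets(gt, cfg64)
        grids = _zero_grids(cfg64)
        anchors = cfg64.anchors_array()
        for s, (gh, gw) in enumerate(cfg64.grid_sizes()):
            for (a, r, c) in np.argwhere(mask.obj[s]):
                aw, ah = anchors[s, a]
                sx = gt[0].cx * gw - c
                sy = gt[0].cy * gh - r
                sw = np.sqrt(gt[0].w * 64 / aw) / 2
                sh = np.sqrt(gt[0].h * 64 / ah) / 2
                assert 0 < sx < 1 and 0 < sy < 1 and 0 < sw < 1 and 0 < sh < 1
                grids[s][0, a, r, c, 0] = _logit(sx)
                grids[s][0, a, r, c, 1] = _logit(sy)
                grids[s][0, a, r, c, 2] = _logit(sw)
                grids[s][0, a, r, c, 3] = _logit(sh)
                grids[s][0, a, r, c, 4] = 40.0      # sigmoid ~ 1
                grids[s][0, a, r, c, 5:] = -40.0
                grids[s][0, a, r, c, 5 + gt[0].class_id] = 40.0
        lb = detection_loss(grids, [mask], LossWeights(), cfg64)
        assert lb.l_obj == pytest.approx(0.0, abs=1e-9)
        assert lb.l_cls == pytest.approx(0.0, abs=1e-9)
        assert lb.l_conf == pytest.approx(0.0, abs=1e-6)

    def test_box_term_hand_sum(self, cfg64):
        """One responsible cell; the squared-difference box loss equals the
        hand-summed (dx^2 + dy^2) + (dw^2 + dh^2) of the decoded box."""
        gt = [BBox(0, 0.39, 0.61, 0.25, 0.22)]
        mask = assign_targets(gt, cfg64)
        # keep exactly one responsible cell to make the hand sum unambiguous
        keep = None
        for s in range(3):
            for arc in np.argwhere(mask.obj[s]):
                if keep is None:
                    keep = (s, tuple(arc))
                else:
                    mask.obj[s][tuple(arc)] = False
        s, (a, r, c) = keep
        grids = _zero_grids(cfg64)
        grids[s][0, a, r, c, :4] = [_logit(0.3), _logit(0.7),
                                    _logit(0.4), _logit(0.5)]
        gh, gw = cfg64.grid_sizes()[s]
        aw, ah = cfg64.anchors_array()[s, a]
        xd = (c + 0.3) / gw
        yd = (r + 0.7) / gh
        wd = (2 * 0.4) ** 2 * aw / 64
        hd = (2 * 0.5) ** 2 * ah / 64
        expected = ((xd - 0.39) ** 2 + (yd - 0.61) ** 2
                    + (wd - 0.25) ** 2 + (hd - 0.22) ** 2)
        lb = detection_loss(grids, [mask], LossWeights(alpha=1, beta=0, gamma=0),
                            cfg64)
        assert lb.l_obj == pytest.approx(expected, abs=1e-9)
        assert lb.total == pytest.approx(expected, abs=1e-9)

    def test_confidence_term_hand_sum(self, cfg64):
        """Obj cell with target 1 and prediction 0.8, one no-object cell at
        0.1, lambda_noobj = 0.5: loss = 0.2^2 + 0.5 * 0.1^2 = 0.045."""
        gt = [BBox(0, 0.5, 0.5, 0.3, 0.3)]
        mask = assign_targets(gt, cfg64)
        keep = None
        for s in range(3):
            for arc in np.argwhere(mask.obj[s]):
                if keep is None:
                    keep = (s, tuple(arc))
                else:
                    mask.obj[s][tuple(arc)] = False
        s, (a, r, c) = keep
        grids = _zero_grids(cfg64)           # all other cells ~ sigmoid(-40)
        grids[s][0, a, r, c, 4] = _logit(0.8)
        noobj_cell = (0, (a + 1) % 3, r, c, 4)
        grids[s][noobj_cell] = _logit(0.1)
        ct = [np.where(m, 1.0, 0.0) for m in
              (np.stack([mask.obj[i]]) for i in range(3))]
        lb = detection_loss(grids, [mask], LossWeights(), cfg64,
                            conf_targets=ct)
        assert lb.l_conf == pytest.approx(0.04 + 0.5 * 0.01, abs=1e-6)

    def test_class_term_hand_sum(self, cfg64):
        """Class probabilities (0.7, 0.2) against one-hot class 0:
        (0.7-1)^2 + (0.2-0)^2 = 0.13."""
        gt = [BBox(0, 0.5, 0.5, 0.3, 0.3)]
        mask = assign_targets(gt, cfg64)
        keep = None
        for s in range(3):
            for arc in np.argwhere(mask.obj[s]):
                if keep is None:
                    keep = (s, tuple(arc))
                else:
                    mask.obj[s][tuple(arc)] = False
        s, (a, r, c) = keep
        grids = _zero_grids(cfg64)
        grids[s][0, a, r, c, 5] = _logit(0.7)
        grids[s][0, a, r, c, 6] = _logit(0.2)
        lb = detection_loss(grids, [mask], LossWeights(alpha=0, beta=1, gamma=0),
                            cfg64)
        assert lb.l_cls == pytest.approx(0.09 + 0.04, abs=1e-9)

    def test_total_linear_in_weights(self, cfg64, rng):
        gt = [BBox(0, 0.5, 0.5, 0.3, 0.3)]
        mask = assign_targets(gt, cfg64)
        grids = [rng.normal(size=(1, 3, gh, gw, 7))
                 for gh, gw in cfg64.grid_sizes()]
        ct = confidence_targets(grids, [mask], cfg64)
        a = detection_loss(grids, [mask], LossWeights(1, 1, 1), cfg64,
                           conf_targets=ct)
        b = detection_loss(grids, [mask], LossWeights(2, 3, 4), cfg64,
                           conf_targets=ct)
        assert b.total == pytest.approx(
            2 * a.l_obj + 3 * a.l_cls + 4 * a.l_conf, rel=1e-9)


class TestNaiveOracleEquivalence:
    def test_triple_loop_matches_vectorized(self, cfg64, rng):
        """A per-(scale, anchor, cell) reference loop reproduces the
        vectorized loss on a random two-image batch to 1e-6."""
        boxes = [[BBox(0, 0.3, 0.4, 0.2, 0.25), BBox(1, 0.7, 0.7, 0.3, 0.2)],
                 [BBox(1, 0.5, 0.2, 0.15, 0.3)]]
        masks = [assign_targets(b, cfg64) for b in boxes]
        grids = [rng.normal(size=(2, 3, gh, gw, 7))
                 for gh, gw in cfg64.grid_sizes()]
        ct = confidence_targets(grids, masks, cfg64)
        w = LossWeights(alpha=0.7, beta=1.3, gamma=0.9, lambda_noobj=0.5)
        lb = detection_loss(grids, masks, w, cfg64, conf_targets=ct)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        l_obj = l_cls = l_conf = 0.0
        for s, pred in enumerate(grids):
            gh, gw = cfg64.grid_sizes()[s]
            anchors = cfg64.anchors_array()[s]
            for n in range(2):
                for a in range(3):
                    for r in range(gh):
                        for c in range(gw):
                            p = pred[n, a, r, c]
                            conf = sig(p[4])
                            if masks[n].obj[s][a, r, c]:
                                tx, ty, tw, th = masks[n].txywh[s][a, r, c]
                                cls = masks[n].cls[s][a, r, c]
                                x = (c + sig(p[0])) / gw
                                y = (r + sig(p[1])) / gh
                                wv = (2 * sig(p[2])) ** 2 * anchors[a, 0] / 64
                                hv = (2 * sig(p[3])) ** 2 * anchors[a, 1] / 64
                                l_obj += (x - tx) ** 2 + (y - ty) ** 2
                                l_obj += (wv - tw) ** 2 + (hv - th) ** 2
                                for k in range(2):
                                    t = 1.0 if k == cls else 0.0
                                    l_cls += (sig(p[5 + k]) - t) ** 2
                                l_conf += (conf - ct[s][n, a, r, c]) ** 2
                            else:
                                l_conf += 0.5 * conf ** 2
        assert lb.l_obj == pytest.approx(l_obj, abs=1e-6)
        assert lb.l_cls == pytest.approx(l_cls, abs=1e-6)
        assert lb.l_conf == pytest.approx(l_conf, abs=1e-6)

    def test_batch_additivity(self, cfg64, rng):
        boxes = [[BBox(0, 0.3, 0.4, 0.2, 0.25)], [BBox(1, 0.5, 0.2, 0.15, 0.3)]]
        masks = [assign_targets(b, cfg64) for b in boxes]
        grids = [rng.normal(size=(2, 3, gh, gw, 7))
                 for gh, gw in cfg64.grid_sizes()]
        whole = detection_loss(grids, masks, LossWeights(), cfg64).total
        parts = sum(
            detection_loss([g[i:i + 1] for g in grids], [masks[i]],
                           LossWeights(), cfg64).total
            for i in range(2))
        assert whole == pytest.approx(parts, rel=1e-9)


class TestGradients:
    def test_finite_difference_match(self, cfg64, rng):
        """Analytic gradient of the total loss w.r.t. individual raw
        predictions agrees with central differences to 1e-3 relative."""
        boxes = [[BBox(0, 0.3, 0.4, 0.2, 0.25), BBox(1, 0.7, 0.7, 0.3, 0.2)]]
        masks = [assign_targets(b, cfg64) for b in boxes]
        grids = [rng.normal(size=(1, 3, gh, gw, 7))
                 for gh, gw in cfg64.grid_sizes()]
        ct = confidence_targets(grids, masks, cfg64)
        w = LossWeights()
        _, grads = detection_loss(grids, masks, w, cfg64, conf_targets=ct,
                                  compute_grad=True)
        obj_cells = np.argwhere(masks[0].obj[0])
        points = [(0, (0, *obj_cells[0], ch)) for ch in range(7)]
        points += [(1, (0, 1, 2, 2, ch)) for ch in range(7)]
        for s, idx in points:
            eps = 1e-6
            up = [g.copy() for g in grids]
            up[s][idx] += eps
            down = [g.copy() for g in grids]
            down[s][idx] -= eps
            fd = (detection_loss(up, masks, w, cfg64, conf_targets=ct).total
                  - detection_loss(down, masks, w, cfg64, conf_targets=ct).total
                  ) / (2 * eps)
            assert grads[s][idx] == pytest.approx(fd, rel=1e-3, abs=1e-8)

    def test_nan_prediction_reported_with_location(self, cfg64):
        grids = _zero_grids(cfg64)
        grids[1][0, 2, 1, 1, 3] = np.nan
        mask = assign_targets([], cfg64)
        with pytest.raises(FloatingPointError, match="scale 1"):
            detection_loss(grids, [mask], LossWeights(), cfg64)


class TestLossBreakdown:
    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            LossBreakdown(l_obj=-1.0, l_cls=0.0, l_conf=0.0, total=0.0)
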