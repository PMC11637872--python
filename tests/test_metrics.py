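"""Decoding, NMS and the evaluation suite against brute-force references."""

import numpy as np
import pytest

from chmmi.boxes import BBox, iou
from chmmi.detector import DetectorConfig
from chmmi.losses import assign_targets
from chmmi.metrics import (Detection, MatchResult, anchor_cell_count,
                           average_precision, decode_predictions, map_suite,
                           match_detections, mcc, nms, precision_recall,
                           roc_curve)


def _det(cls, score, cx, cy, w, h, img="0"):
    return Detection(img, cls, score, BBox(cls, cx, cy, w, h))


@pytest.fixture(scope="module")
def cfg64():
    return DetectorConfig(n_classes=2, input_size=(64, 64),
                          widths=(4, 6, 8, 10, 12), seed=0)


class TestDecode:
    def test_suppressed_objectness_gives_no_detections(self, cfg64):
        grids = [np.zeros((1, 3, gh, gw, 7)) for gh, gw in cfg64.grid_sizes()]
        for g in grids:
            g[..., 4] = -50.0
        assert decode_predictions(grids, cfg64, 0.25) == []

    def test_score_is_objectness_times_class_probability(self, cfg64):
        grids = [np.full((1, 3, gh, gw, 7), -50.0)
                 for gh, gw in cfg64.grid_sizes()]
        g = grids[2]
        g[0, 0, 1, 1, :] = 0.0
        g[0, 0, 1, 1, 4] = 50.0                      # objectness ~ 1
        g[0, 0, 1, 1, 5] = np.log(0.7 / 0.3)         # class prob 0.7
        g[0, 0, 1, 1, 6] = -50.0
        dets = decode_predictions(grids, cfg64, 0.25)
        assert len(dets) == 1
        assert dets[0].score == pytest.approx(0.7, abs=1e-6)
        assert dets[0].class_id == 0

    def test_encode_decode_roundtrip(self, cfg64):
        """A raw grid encoding a GT box at its responsible cell decodes back
        to that box with IoU > 0.99."""
        gt = BBox(1, 0.41, 0.63, 0.22, 0.27)
        mask = assign_targets([gt], cfg64)
        grids = [np.full((1, 3, gh, gw, 7), -50.0)
                 for gh, gw in cfg64.grid_sizes()]
        anchors = cfg64.anchors_array()
        placed = False
        for s, (gh, gw) in enumerate(cfg64.grid_sizes()):
            for (a, r, c) in np.argwhere(mask.obj[s]):
                aw, ah = anchors[s, a]
                sw = np.sqrt(gt.w * 64 / aw) / 2
                sh = np.sqrt(gt.h * 64 / ah) / 2
                if not (0 < sw < 1 and 0 < sh < 1):
                    continue
                logit = lambda p: np.log(p / (1 - p))
                grids[s][0, a, r, c, 0] = logit(gt.cx * gw - c)
                grids[s][0, a, r, c, 1] = logit(gt.cy * gh - r)
                grids[s][0, a, r, c, 2] = logit(sw)
                grids[s][0, a, r, c, 3] = logit(sh)
                grids[s][0, a, r, c, 4] = 50.0
                grids[s][0, a, r, c, 5 + gt.class_id] = 50.0
                placed = True
        assert placed
        dets = decode_predictions(grids, cfg64, 0.25)
        assert any(iou(d.box, gt) > 0.99 and d.class_id == 1 for d in dets)


class TestNms:
    def test_duplicate_suppressed(self):
        a = _det(0, 0.9, 0.5, 0.5, 0.2, 0.2)
        b = _det(0, 0.8, 0.5, 0.5, 0.2, 0.2)
        kept = nms([b, a], 0.45)
        assert kept == [a]

    def test_disjoint_survive(self):
        a = _det(0, 0.9, 0.2, 0.2, 0.1, 0.1)
        b = _det(0, 0.8, 0.8, 0.8, 0.1, 0.1)
        assert len(nms([a, b], 0.45)) == 2

    def test_different_classes_not_suppressed(self):
        a = _det(0, 0.9, 0.5, 0.5, 0.2, 0.2)
        b = _det(1, 0.8, 0.5, 0.5, 0.2, 0.2)
        assert len(nms([a, b], 0.45)) == 2

    def test_matches_brute_force_reference(self, rng):
        """Greedy NMS equals an O(n^2) reference on random boxes, and the
        result is independent of input order."""
        dets = [_det(int(rng.integers(2)), float(rng.uniform(0.1, 1)),
                     *rng.uniform(0.2, 0.8, 2), *rng.uniform(0.05, 0.3, 2))
                for _ in range(10)]

        def brute(ds, thresh):
            order = sorted(ds, key=lambda d: (-d.score, d.box.cx, d.box.cy,
                                              d.box.w, d.box.h, d.class_id))
            keep = []
            for d in order:
                ok = True
                for k in keep:
                    if k.class_id == d.class_id and iou(k.box, d.box) >= thresh:
                        ok = False
                keep.append(d) if ok else None
            return keep

        ref = brute(dets, 0.45)
        assert nms(dets, 0.45) == ref
        shuffled = [dets[i] for i in rng.permutation(len(dets))]
        assert nms(shuffled, 0.45) == ref


class TestMatching:
    def test_perfect_detections(self):
        gt = {"0": [BBox(0, 0.5, 0.5, 0.2, 0.2), BBox(1, 0.2, 0.2, 0.1, 0.1)]}
        dets = [_det(0, 1.0, 0.5, 0.5, 0.2, 0.2), _det(1, 1.0, 0.2, 0.2, 0.1, 0.1)]
        res = match_detections(dets, gt, 0.5)
        assert res[0].tp == 1 and res[0].fp == 0 and res[0].fn == 0
        assert res[1].tp == 1

    def test_detection_without_gt_is_fp(self):
        res = match_detections([_det(0, 0.9, 0.5, 0.5, 0.2, 0.2)], {"0": []}, 0.5)
        assert res[0].fp == 1 and res[0].tp == 0

    def test_greedy_prefers_higher_score(self):
        gt = {"0": [BBox(0, 0.5, 0.5, 0.2, 0.2)]}
        hi = _det(0, 0.9, 0.5, 0.5, 0.2, 0.2)
        lo = _det(0, 0.8, 0.51, 0.5, 0.2, 0.2)
        res = match_detections([lo, hi], gt, 0.5)
        assert res[0].tp == 1 and res[0].fp == 1
        assert res[0].flags == [True, False]  # score-descending order

    def test_count_conservation(self, rng):
        gt = {"0": [BBox(0, *rng.uniform(0.3, 0.7, 2), 0.2, 0.2)
                    for _ in range(5)]}
        dets = [_det(0, float(rng.uniform()), *rng.uniform(0.2, 0.8, 2), 0.2, 0.2)
                for _ in range(8)]
        res = match_detections(dets, gt, 0.5)[0]
        assert res.tp + res.fn == 5
        assert res.tp + res.fp == 8


class TestPrecisionRecall:
    def test_values(self):
        m = MatchResult(tp=90, fp=10, fn=15, flags=[], scores=[], n_gt=105)
        p, r = precision_recall(m)
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(90 / 105)

    def test_empty_conventions(self):
        m = MatchResult(tp=0, fp=0, fn=0, flags=[], scores=[], n_gt=0)
        assert precision_recall(m) == (0.0, 1.0)


class TestAveragePrecision:
    def test_ranked_example(self):
        assert average_precision([True, False, True], 2) == pytest.approx(
            0.5 * 1.0 + 0.5 * (2 / 3))

    def test_perfect(self):
        assert average_precision([True, True, True], 3) == 1.0

    def test_no_tp(self):
        assert average_precision([False, False], 4) == 0.0

    def test_no_gt_excluded(self):
        assert average_precision([False], 0) is None

    def test_coco101_close_to_all_point_on_dense_curve(self, rng):
        flags = list(rng.random(400) < 0.6)
        ap_a = average_precision(flags, 240, "all_point")
        ap_c = average_precision(flags, 240, "coco101")
        assert ap_c == pytest.approx(ap_a, abs=0.02)


class TestMcc:
    def test_perfect(self):
        assert mcc(10, 10, 0, 0) == 1.0

    def test_hand_value(self):
        expected = 7500 / np.sqrt(100 * 105 * 95 * 100)
        assert mcc(90, 85, 10, 15) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry(self):
        assert mcc(90, 85, 10, 15) == pytest.approx(-mcc(15, 10, 85, 90))

    def test_zero_denominator(self):
        assert mcc(0, 0, 0, 5) == 0.0


class TestRoc:
    def test_perfect_detector(self):
        gt = {"0": [BBox(0, 0.5, 0.5, 0.2, 0.2)]}
        dets = [_det(0, 1.0, 0.5, 0.5, 0.2, 0.2)]
        pts, auc, degenerate = roc_curve(dets, gt, total_cells=100)
        assert auc == pytest.approx(1.0)
        assert not degenerate

    def test_silent_detector_flagged(self):
        gt = {"0": [BBox(0, 0.5, 0.5, 0.2, 0.2)]}
        pts, auc, degenerate = roc_curve([], gt, total_cells=100)
        assert degenerate
        assert auc == pytest.approx(0.5)

    def test_tpr_non_increasing_in_threshold(self, rng):
        gt = {"0": [BBox(0, *rng.uniform(0.3, 0.7, 2), 0.2, 0.2)
                    for _ in range(6)]}
        dets = [_det(0, float(rng.uniform(0.05, 1.0)),
                     *rng.uniform(0.25, 0.75, 2), 0.2, 0.2) for _ in range(20)]
        pts, _, _ = roc_curve(dets, gt, total_cells=500)
        tprs = [tpr for _, _, tpr in pts]  # thresholds ascending
        assert all(a >= b - 1e-12 for a, b in zip(tprs, tprs[1:]))


class TestMapSuite:
    def _perfect(self):
        gt = {"0": [BBox(0, 0.5, 0.5, 0.2, 0.2)],
              "1": [BBox(1, 0.3, 0.3, 0.2, 0.2)]}
        dets = [_det(0, 1.0, 0.5, 0.5, 0.2, 0.2, img="0"),
                _det(1, 1.0, 0.3, 0.3, 0.2, 0.2, img="1")]
        return dets, gt

    def test_perfect_scores_one(self):
        dets, gt = self._perfect()
        rep = map_suite(dets, gt, 2)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(1.0)

    def test_iou_06_counts_at_05_not_075(self):
        gt = {"0": [BBox(0, 0.5, 0.5, 0.3, 0.2)]}
        shifted = BBox(0, 0.55, 0.5, 0.3, 0.2)   # IoU = 2/4 ... compute below
        v = iou(shifted, gt["0"][0])
        assert 0.5 < v < 0.75
        rep = map_suite([Detection("0", 0, 0.9, shifted)], gt, 1)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 < rep.map50

    def test_class_relabel_invariance(self, rng):
        gt = {"0": [BBox(0, 0.3, 0.3, 0.2, 0.2), BBox(1, 0.7, 0.7, 0.2, 0.2)]}
        dets = [_det(0, 0.9, 0.31, 0.3, 0.2, 0.2), _det(1, 0.8, 0.7, 0.72, 0.2, 0.2),
                _det(0, 0.6, 0.1, 0.1, 0.1, 0.1)]
        rep = map_suite(dets, gt, 2)
        swap = lambda c: 1 - c
        gt2 = {"0": [BBox(swap(b.class_id), b.cx, b.cy, b.w, b.h)
                     for b in gt["0"]]}
        dets2 = [Detection(d.image_id, swap(d.class_id), d.score,
                           BBox(swap(d.class_id), d.box.cx, d.box.cy,
                                d.box.w, d.box.h)) for d in dets]
        rep2 = map_suite(dets2, gt2, 2)
        assert rep2.map50 == pytest.approx(rep.map50)
        assert rep2.map50_95 == pytest.approx(rep.map50_95)

    def test_rank_preserving_score_rescale_invariance(self):
        gt = {"0": [BBox(0, 0.3, 0.3, 0.2, 0.2), BBox(0, 0.7, 0.7, 0.2, 0.2)]}
        dets = [_det(0, 0.9, 0.3, 0.3, 0.2, 0.2), _det(0, 0.5, 0.1, 0.1, 0.1, 0.1),
                _det(0, 0.4, 0.7, 0.7, 0.2, 0.2)]
        rep = map_suite(dets, gt, 1, score_thresh=0.0)
        rescaled = [Detection(d.image_id, d.class_id, d.score / 2, d.box)
                    for d in dets]
        rep2 = map_suite(rescaled, gt, 1, score_thresh=0.0)
        assert rep2.map50 == pytest.approx(rep.map50)
        assert rep2.map50_95 == pytest.approx(rep.map50_95)


def test_anchor_cell_count():
    cfg = DetectorConfig(n_classes=2, input_size=(64, 64))
    # 3 anchors x (8x8 + 4x4 + 2x2) cells per image
    assert anchor_cell_count(cfg, 5) == 5 * 3 * (64 + 16 + 4)
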