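"""Detection metrics: matching protocol, AP integration, summaries."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pytest

from lsnet.boxes import BBox, Detection
from lsnet.evaluation import (MatchResult, average_precision, evaluate,
                              f1_curve, match_detections, precision_recall_curve,
                              summary_metrics)


def det(cx, cy, w, h, cls, conf):
    return Detection(BBox(cx, cy, w, h), cls, conf)


class TestMatching:
    def test_perfect_detections_all_tp(self):
        gts = [BBox(10, 10, 8, 8, 0), BBox(40, 40, 8, 8, 1)]
        dets = [det(10, 10, 8, 8, 0, 0.9), det(40, 40, 8, 8, 1, 0.8)]
        m = match_detections(dets, gts)
        assert m.tp.all()
        assert m.num_gt == {0: 1, 1: 1}

    def test_one_to_one_rule(self):
        """Two detections on one ground truth: one TP, one FP."""
        gts = [BBox(10, 10, 8, 8, 0)]
        dets = [det(10, 10, 8, 8, 0, 0.9), det(10.5, 10, 8, 8, 0, 0.8)]
        m = match_detections(dets, gts)
        assert m.tp.tolist() == [True, False]

    def test_iou_exactly_at_threshold_is_tp(self):
        """The match rule is >=, checked at an exactly-0.5 overlap."""
        gt = BBox.from_xyxy(0, 0, 10, 10, class_id=0)
        # corners (0,0)-(10,5): intersection 50, union 100 -> IoU 0.5
        d = det(5, 2.5, 10, 5, 0, 0.9)
        m = match_detections([d], [gt], iou_thresh=0.5)
        assert m.tp.tolist() == [True]
        m2 = match_detections([d], [gt], iou_thresh=0.5 + 1e-9)
        assert m2.tp.tolist() == [False]

    def test_class_mismatch_is_fp(self):
        m = match_detections([det(10, 10, 8, 8, 1, 0.9)], [BBox(10, 10, 8, 8, 0)])
        assert not m.tp.any()

    def test_confidence_priority_with_tie_on_gt(self):
        """The higher-confidence detection claims the ground truth."""
        gts = [BBox(10, 10, 10, 10, 0)]
        weak = det(11, 10, 10, 10, 0, 0.5)
        strong = det(12, 10, 10, 10, 0, 0.9)
        m = match_detections([weak, strong], gts)
        assert m.tp.tolist() == [False, True]


class TestAveragePrecision:
    def test_all_tp_covering_all_gt(self):
        m = MatchResult(np.array([True, True]), np.array([0.9, 0.8]),
                        np.zeros(2, int), {0: 2})
        assert average_precision(m, 0) == pytest.approx(1.0)

    def test_hand_constructed_curve(self):
        """TP(.9), FP(.8), TP(.7) over 2 GTs: AP = .5 + .5 * 2/3."""
        m = MatchResult(np.array([True, False, True]), np.array([0.9, 0.8, 0.7]),
                        np.zeros(3, int), {0: 2})
        assert average_precision(m, 0) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_no_detections_is_zero(self):
        m = MatchResult(np.zeros(0, bool), np.zeros(0), np.zeros(0, int), {0: 3})
        assert average_precision(m, 0) == 0.0

    def test_no_ground_truth_is_nan_with_warning(self):
        m = MatchResult(np.array([False]), np.array([0.9]), np.zeros(1, int), {})
        with pytest.warns(UserWarning):
            assert np.isnan(average_precision(m, 0))

    def test_eleven_point_close_to_all_points(self):
        m = MatchResult(np.array([True, False, True, True]),
                        np.array([0.9, 0.85, 0.7, 0.6]), np.zeros(4, int), {0: 3})
        ap = average_precision(m, 0)
        ap11 = average_precision(m, 0, interpolation="eleven_point")
        assert abs(ap - ap11) < 0.15

    @staticmethod
    def brute_force_ap(tp: np.ndarray, conf: np.ndarray, n_gt: int) -> float:
        """Independent oracle: precision envelope integrated over every
        distinct recall level, built point by point."""
        order = np.argsort(-conf, kind="stable")
        tp = tp[order]
        ap = 0.0
        prev_recall = 0.0
        for k in range(1, len(tp) + 1):
            tps = int(tp[:k].sum())
            recall = tps / n_gt
            if recall > prev_recall:
                # best precision at any cutoff j >= k reaching this recall
                best = 0.0
                for j in range(k, len(tp) + 1):
                    pj = tp[:j].sum() / j
                    rj = tp[:j].sum() / n_gt
                    if rj >= recall:
                        best = max(best, pj)
                ap += (recall - prev_recall) * best
                prev_recall = recall
        return ap

    def test_matches_brute_force_on_all_small_configurations(self):
        """All-point AP equals exhaustive PR integration for every TP/FP
        pattern of up to 6 detections over up to 3 ground truths."""
        conf = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        checked = 0
        for n_det in range(0, 7):
            for flags in itertools.product([False, True], repeat=n_det):
                tp = np.array(flags, dtype=bool)
                for n_gt in range(1, 4):
                    if tp.sum() > n_gt:
                        continue
                    m = MatchResult(tp, conf[:n_det], np.zeros(n_det, int),
                                    {0: n_gt})
                    ap = average_precision(m, 0)
                    oracle = self.brute_force_ap(tp, conf[:n_det], n_gt)
                    assert ap == pytest.approx(oracle, abs=1e-12), (flags, n_gt)
                    checked += 1
        assert checked == 189   # all flag patterns over all gt counts

    def test_invariant_to_monotone_confidence_transform(self):
        rng = np.random.default_rng(3)
        tp = rng.random(20) < 0.5
        conf = rng.uniform(0.1, 0.9, 20)
        m1 = MatchResult(tp, conf, np.zeros(20, int), {0: 12})
        m2 = MatchResult(tp, conf ** 3 * 0.5, np.zeros(20, int), {0: 12})
        assert average_precision(m1, 0) == pytest.approx(average_precision(m2, 0))

    def test_removing_fp_never_decreases_ap(self):
        rng = np.random.default_rng(4)
        tp = rng.random(15) < 0.5
        conf = rng.uniform(0.1, 0.9, 15)
        base = average_precision(MatchResult(tp, conf, np.zeros(15, int), {0: 10}), 0)
        fps = np.flatnonzero(~tp)
        keep = np.ones(15, bool)
        keep[fps[0]] = False
        pruned = average_precision(
            MatchResult(tp[keep], conf[keep], np.zeros(14, int), {0: 10}), 0)
        assert pruned >= base - 1e-12

    def test_removing_tp_never_increases_ap(self):
        rng = np.random.default_rng(5)
        tp = rng.random(15) < 0.6
        conf = rng.uniform(0.1, 0.9, 15)
        base = average_precision(MatchResult(tp, conf, np.zeros(15, int), {0: 10}), 0)
        tps = np.flatnonzero(tp)
        keep = np.ones(15, bool)
        keep[tps[0]] = False
        pruned = average_precision(
            MatchResult(tp[keep], conf[keep], np.zeros(14, int), {0: 10}), 0)
        assert pruned <= base + 1e-12


class TestSummaries:
    def test_map_is_unweighted_mean(self):
        m = MatchResult(np.array([True, True, False]), np.array([0.9, 0.8, 0.7]),
                        np.array([0, 1, 1]), {0: 1, 1: 2})
        s = summary_metrics(m, [0, 1])
        expected = np.mean([s["per_class"][0]["ap"], s["per_class"][1]["ap"]])
        assert s["map"] == pytest.approx(expected)

    def test_single_class_map_equals_its_ap(self):
        m = MatchResult(np.array([True]), np.array([0.9]), np.zeros(1, int), {0: 1})
        s = summary_metrics(m, [0])
        assert s["map"] == pytest.approx(s["per_class"][0]["ap"])

    def test_f1_from_precision_recall_rounds_as_published(self):
        # harmonic mean of the survey's cattle precision/recall prints as 0.93
        p, r = 0.9251, 0.9279
        assert round(2 * p * r / (p + r), 2) == 0.93

    def test_f1_curve_shape(self):
        m = MatchResult(np.array([True, False, True, True]),
                        np.array([0.9, 0.8, 0.7, 0.6]), np.zeros(4, int), {0: 3})
        conf, f1 = f1_curve(m, 0)
        assert conf.shape == f1.shape == (4,)
        assert np.all((f1 >= 0) & (f1 <= 1))
        best = summary_metrics(m, [0])["per_class"][0]["f1"]
        assert best == pytest.approx(f1.max())

    def test_evaluate_end_to_end(self):
        gts = [[BBox(10, 10, 8, 8, 0), BBox(40, 40, 8, 8, 1)], [BBox(20, 20, 8, 8, 0)]]
        dets = [[det(10, 10, 8, 8, 0, 0.9)], [det(20, 20, 8, 8, 0, 0.8),
                                              det(60, 60, 8, 8, 1, 0.7)]]
        res = evaluate(dets, gts)
        assert res["per_class"][0]["ap"] == pytest.approx(1.0)
        assert res["per_class"][1]["ap"] == pytest.approx(0.0)
        assert res["map"] == pytest.approx(0.5)
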