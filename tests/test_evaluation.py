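import itertools

import numpy as np
import pytest

from koadet.config import EvalConfig
from koadet.evaluation import (average_precision, confusion_matrix,
                               evaluate_detections, fps, match_detections,
                               mean_average_precision, precision_recall)
from koadet.geometry import Box, Detection, iou

from conftest import random_box


class TestMatchDetections:
    def test_exact_overlap_is_tp(self):
        out = match_detections([Detection(Box(0, 0, 4, 4), 1, 0.9)],
                               [(Box(0, 0, 4, 4), 1)])
        assert out.tp == 1 and out.fp == 0 and out.fn == 0

    def test_low_iou_is_fp_and_fn(self):
        # IoU = 4/16+... below 0.5: detection invalid, gt unmatched
        det = Detection(Box(0, 0, 2, 2), 1, 0.9)
        gt = [(Box(1, 1, 3, 3), 1)]
        assert iou(det.box, gt[0][0]) < 0.5
        out = match_detections([det], gt)
        assert out.tp == 0 and out.fp == 1 and out.fn == 1

    def test_exact_threshold_is_invalid(self):
        # IoU exactly 0.5 must not count (strictly greater required)
        det = Detection(Box(0, 0, 2, 4), 0, 0.9)
        gt = [(Box(0, 0, 4, 4), 0)]
        assert iou(det.box, gt[0][0]) == pytest.approx(0.5)
        out = match_detections([det], gt, 0.5)
        assert out.tp == 0

    def test_wrong_class_never_matches(self):
        out = match_detections([Detection(Box(0, 0, 4, 4), 2, 0.9)],
                               [(Box(0, 0, 4, 4), 1)])
        assert out.tp == 0 and out.fn == 1

    def test_matches_greedy_oracle(self):
        rng = np.random.default_rng(71)
        dets = [Detection(Box(*random_box(rng, hi=12, min_size=2)),
                          int(rng.integers(0, 2)), float(rng.random()))
                for _ in range(5)]
        gts = [(Box(*random_box(rng, hi=12, min_size=2)),
                int(rng.integers(0, 2))) for _ in range(3)]
        out = match_detections(dets, gts, 0.3)
        # independent re-derivation of the same greedy order
        taken = set()
        expect_tp = []
        for i in sorted(range(5), key=lambda i: (-dets[i].score, i)):
            best, best_iou = None, 0.3
            for j, (gb, gl) in enumerate(gts):
                if j in taken or gl != dets[i].label:
                    continue
                ov = iou(dets[i].box, gb)
                if ov > best_iou:
                    best, best_iou = j, ov
            if best is not None:
                taken.add(best)
            expect_tp.append(best is not None)
        assert out.tp_flags.tolist() == expect_tp

    def test_tp_sets_nested_across_thresholds(self):
        """Raising the IoU threshold can only demote detections (TP@0.75 is a
        subset of TP@0.5) in the post-NMS regime where each ground truth is
        claimed by at most one detection."""
        rng = np.random.default_rng(73)
        for _ in range(20):
            gts, dets = [], []
            for k in range(4):
                gb = Box(*random_box(rng, hi=60, min_size=5))
                cls = int(rng.integers(0, 3))
                gts.append((gb, cls))
                jit = rng.uniform(-1.5, 1.5, 4)
                dets.append(Detection(
                    Box(gb.x_min + jit[0], gb.y_min + jit[1],
                        max(gb.x_max + jit[2], gb.x_min + jit[0] + 1),
                        max(gb.y_max + jit[3], gb.y_min + jit[1] + 1)),
                    cls, float(rng.random())))
            # plus background false positives far from every gt
            for _ in range(3):
                dets.append(Detection(Box(*random_box(rng, lo=80, hi=100)),
                                      int(rng.integers(0, 3)),
                                      float(rng.random())))
            o50 = match_detections(dets, gts, 0.5)
            o75 = match_detections(dets, gts, 0.75)
            tp50 = {int(i) for i, t in zip(o50.order, o50.tp_flags) if t}
            tp75 = {int(i) for i, t in zip(o75.order, o75.tp_flags) if t}
            assert tp75 <= tp50


class TestPrecisionRecall:
    def test_arithmetic(self):
        out = match_detections(
            [Detection(Box(0, 0, 4, 4), 0, 0.9)], [(Box(0, 0, 4, 4), 0)])
        assert precision_recall(out) == (1.0, 1.0)

    def test_degenerate_conventions(self):
        out = match_detections([], [])
        assert precision_recall(out) == (0.0, 1.0)


class TestAveragePrecision:
    def test_single_correct_detection(self):
        assert average_precision([0.9], [True], 1) == 1.0

    def test_hand_traced_interpolation(self):
        # 2 gt; score order TP, FP, TP -> PR (0.5,1.0),(0.5,0.5),(1.0,2/3)
        ap = average_precision([0.9, 0.8, 0.7], [True, False, True], 2)
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(79)
        scores = rng.random(12)
        flags = rng.random(12) < 0.5
        n_gt = 6
        ap = average_precision(scores, flags, n_gt)
        # oracle: exhaustive interpolation over every achievable recall level
        order = np.argsort(-scores)
        tp = np.cumsum(np.asarray(flags)[order])
        fp = np.cumsum(~np.asarray(flags)[order])
        rec, prec = tp / n_gt, tp / (tp + fp)
        expect = 0.0
        prev_r = 0.0
        for r in sorted(set(rec)):
            p_max = max(p for rr, p in zip(rec, prec) if rr >= r)
            expect += (r - prev_r) * p_max
            prev_r = r
        assert ap == pytest.approx(expect, abs=1e-9)

    def test_rank_statistic_invariance(self):
        scores = [0.9, 0.6, 0.3]
        flags = [True, False, True]
        a = average_precision(scores, flags, 2)
        b = average_precision([s * 0.5 + 0.1 for s in scores], flags, 2)
        assert a == b

    def test_zero_score_fp_never_increases_ap(self):
        base = average_precision([0.9, 0.7], [True, True], 3)
        worse = average_precision([0.9, 0.7, 0.0], [True, True, False], 3)
        assert worse <= base

    def test_undefined_without_gt(self):
        assert average_precision([0.5], [False], 0) is None


class TestMeanAP:
    def test_mean_and_single(self):
        assert mean_average_precision({"a": 1.0, "b": 0.5}) == 0.75
        assert mean_average_precision([0.7]) == pytest.approx(0.7)

    def test_permutation_invariant_and_none_excluded(self):
        assert mean_average_precision({"a": 0.4, "b": None, "c": 0.8}) == \
            pytest.approx(0.6)
        for perm in itertools.permutations([1.0, 0.5, 0.25]):
            assert mean_average_precision(list(perm)) == pytest.approx(7 / 12)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision({"a": None})


class TestFps:
    def test_worked_example(self):
        assert fps(0.05) == pytest.approx(20.0)

    def test_unit_and_round_trip(self):
        assert fps(1.0) == 1.0
        assert fps(1.0 / fps(0.37)) == pytest.approx(fps(1.0 / fps(0.37)),
                                                     abs=1e-12)
        assert fps(1.0 / fps(0.37)) == pytest.approx(1 / 0.37, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fps(0.0)


class TestConfusionMatrix:
    def test_perfect_detector_gives_identity(self):
        dets, gts = [], []
        for c in range(5):
            box = Box(0, 0, 4 + c, 4 + c)
            dets.append([Detection(box, c, 0.9)])
            gts.append([(box, c)])
        m = confusion_matrix(dets, gts)
        assert np.allclose(m[:, :5], np.eye(5))
        assert np.allclose(m[:, 5], 0)

    def test_wrong_class_right_place_zero_diagonal(self):
        dets, gts = [], []
        for c in range(5):
            box = Box(0, 0, 6, 6)
            dets.append([Detection(box, (c + 1) % 5, 0.9)])
            gts.append([(box, c)])
        m = confusion_matrix(dets, gts)
        assert np.allclose(np.diag(m[:, :5]), 0)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_hand_tallied_toy(self):
        rng = np.random.default_rng(83)
        dets, gts = [], []
        expected = np.zeros((5, 6))
        for k in range(10):
            g = k % 5
            box = Box(*random_box(rng, hi=20, min_size=4))
            gts.append([(box, g)])
            if k % 3 == 0:
                dets.append([])                       # miss
                expected[g, 5] += 1
            else:
                pred = (g + k) % 5
                dets.append([Detection(box, pred, 0.8)])
                expected[g, pred] += 1
        rows = expected.sum(axis=1, keepdims=True)
        assert np.allclose(confusion_matrix(dets, gts), expected / rows)


class TestRendering:
    def test_pr_and_confusion_figures_written(self, tmp_path):
        rng = np.random.default_rng(97)
        all_dets, all_gts = [], []
        for c in range(5):
            box = Box(*random_box(rng, hi=30, min_size=6))
            all_gts.append([(box, c)])
            all_dets.append([Detection(box, c, 0.9)])
        report = evaluate_detections(all_dets, all_gts, EvalConfig())
        from koadet.evaluation import plot_confusion, plot_pr_curves

        plot_pr_curves(report, tmp_path / "pr.png")
        plot_confusion(report, tmp_path / "cm.png")
        assert (tmp_path / "pr.png").stat().st_size > 0
        assert (tmp_path / "cm.png").stat().st_size > 0


class TestEvaluateDetections:
    def test_report_structure_and_monotonicity(self):
        rng = np.random.default_rng(89)
        all_dets, all_gts = [], []
        for _ in range(10):
            gb = Box(*random_box(rng, hi=30, min_size=6))
            cls = int(rng.integers(0, 5))
            all_gts.append([(gb, cls)])
            jit = rng.uniform(-1, 1, 4)
            all_dets.append([Detection(
                Box(gb.x_min + jit[0], gb.y_min + jit[1],
                    gb.x_max + jit[2], gb.y_max + jit[3]), cls,
                float(rng.uniform(0.3, 1.0)))])
        report = evaluate_detections(all_dets, all_gts, EvalConfig())
        assert set(report.map_at) == {0.5, 0.75}
        assert 0.0 <= report.map_at[0.75] <= report.map_at[0.5] <= 1.0
        for thr, aps in report.per_class_ap.items():
            for v in aps.values():
                assert v is None or 0.0 <= v <= 1.0
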