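import math

import numpy as np
import pytest

from koadet import nn
from koadet.config import LossConfig
from koadet.geometry import Box, iou
from koadet.losses import (ClassificationLossConfig, ciou_aspect_gradients,
                           ciou_loss, diou_loss, eiou_loss, eiou_loss_t,
                           focal_classification_loss, focal_loss_t, giou_loss,
                           total_loss, weighted_bce)

from conftest import random_box


class TestEIoU:
    def test_perfect_prediction_is_zero(self):
        b = Box(0, 0, 4, 4)
        c = eiou_loss(b, b)
        assert c.iou_term == c.distance_term == c.aspect_term == 0.0

    def test_hand_evaluated_components(self):
        # disjoint corner boxes: IoU=0; hull (0,0,4,4) diag^2=32; centers
        # (1,1),(3,3) -> rho^2=8 -> distance 0.25; equal edges -> aspect 0
        c = eiou_loss(Box(0, 0, 2, 2), Box(2, 2, 4, 4))
        assert c.iou_term == pytest.approx(1.0)
        assert c.distance_term == pytest.approx(8 / 32)
        assert c.aspect_term == pytest.approx(0.0)
        assert c.total == pytest.approx(1.25)

    def test_total_dominates_iou_loss(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            p, g = Box(*random_box(rng)), Box(*random_box(rng))
            c = eiou_loss(p, g)
            assert c.total >= 1.0 - iou(p, g) - 1e-12
            centers_match = p.center == pytest.approx(g.center)
            edges_match = (p.width, p.height) == pytest.approx((g.width, g.height))
            if not (centers_match and edges_match):
                assert c.total > 1.0 - iou(p, g)

    def test_translation_invariance_and_scale_covariance(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            p, g = Box(*random_box(rng)), Box(*random_box(rng))
            base = eiou_loss(p, g).total
            dx, dy = rng.uniform(-30, 30, 2)
            shifted = eiou_loss(
                Box(p.x_min + dx, p.y_min + dy, p.x_max + dx, p.y_max + dy),
                Box(g.x_min + dx, g.y_min + dy, g.x_max + dx, g.y_max + dy))
            assert shifted.total == pytest.approx(base, rel=1e-9)
            k = rng.uniform(0.5, 3.0)
            scaled = eiou_loss(Box(*(k * v for v in p.as_tuple())),
                               Box(*(k * v for v in g.as_tuple())))
            assert scaled.total == pytest.approx(base, rel=1e-9)

    def test_degenerate_enclosing_box(self):
        pt = Box(3, 3, 3, 3)
        assert eiou_loss(pt, pt).total == 0.0
        with pytest.raises(ValueError):
            eiou_loss(Box(0, 3, 0, 3), Box(0, 5, 0, 7))

    def test_tensor_version_matches_scalar(self):
        rng = np.random.default_rng(31)
        preds = [random_box(rng) for _ in range(32)]
        gts = [random_box(rng) for _ in range(32)]
        t = eiou_loss_t(nn.Tensor(np.array(preds, dtype=np.float32)),
                        np.array(gts, dtype=np.float32))
        for k in range(32):
            expect = eiou_loss(Box(*preds[k]), Box(*gts[k])).total
            assert float(t.data[k]) == pytest.approx(expect, rel=2e-3, abs=2e-3)


class TestCIoU:
    def test_perfect_prediction_is_zero(self):
        b = Box(0, 0, 4, 4)
        assert ciou_loss(b, b) == pytest.approx(0.0, abs=1e-6)

    def test_aspect_gradients_have_opposite_signs(self):
        dv_dw, dv_dh = ciou_aspect_gradients(Box(0, 0, 4, 2), Box(0, 0, 2, 2))
        assert dv_dw * dv_dh < 0

    def test_equal_aspect_ratio_reduces_to_diou(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            x1, y1 = rng.uniform(0, 10, 2)
            w = rng.uniform(1, 5)
            ar = rng.uniform(0.5, 2.0)
            p = Box(x1, y1, x1 + w, y1 + w * ar)
            gx, gy = rng.uniform(0, 10, 2)
            gw = rng.uniform(1, 5)
            g = Box(gx, gy, gx + gw, gy + gw * ar)
            assert ciou_loss(p, g) == pytest.approx(diou_loss(p, g), abs=1e-6)

    def test_zero_size_gt_rejected(self):
        with pytest.raises(ValueError):
            ciou_loss(Box(0, 0, 2, 2), Box(1, 1, 1, 3))


class TestFocal:
    def test_reduces_to_bce_when_unfocused(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(0.05, 0.95, size=50)
        t = (rng.random(50) < 0.3).astype(float)
        cfg = ClassificationLossConfig(gamma=0.0, alpha=0.0)
        got = focal_classification_loss(p, t, cfg)
        pt = np.where(t > 0.5, p, 1 - p)
        expect = float(-np.log(pt).sum() / max(t.sum(), 1))
        assert got == pytest.approx(expect, rel=1e-9)

    def test_hand_arithmetic_single_positive(self):
        cfg = ClassificationLossConfig(gamma=2.0, alpha=0.0)
        got = focal_classification_loss(np.array([0.5]), np.array([1.0]), cfg)
        assert got == pytest.approx(0.25 * math.log(2), rel=1e-9)

    def test_easy_negatives_are_suppressed(self):
        cfg = ClassificationLossConfig(gamma=2.0, alpha=0.5)
        p_pos = np.array([0.7])
        base = focal_classification_loss(
            np.concatenate([p_pos, np.full(100, 1e-7)]),
            np.concatenate([[1.0], np.zeros(100)]), cfg)
        doubled = focal_classification_loss(
            np.concatenate([p_pos, np.full(200, 1e-7)]),
            np.concatenate([[1.0], np.zeros(200)]), cfg)
        assert abs(doubled - base) < 1e-6

    def test_monotone_decreasing_in_pt(self):
        cfg = ClassificationLossConfig(gamma=2.0, alpha=0.5)
        ps = np.linspace(0.05, 0.95, 30)
        losses = [focal_classification_loss(np.array([p]), np.array([1.0]), cfg)
                  for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_out_of_range_probabilities_clamped_not_rejected(self):
        cfg = ClassificationLossConfig()
        val = focal_classification_loss(np.array([0.0, 1.0]),
                                        np.array([1.0, 0.0]), cfg)
        assert np.isfinite(val)

    def test_tensor_version_matches_numpy(self):
        rng = np.random.default_rng(43)
        p = rng.uniform(0.05, 0.95, size=(20, 5)).astype(np.float32)
        t = (rng.random((20, 5)) < 0.1).astype(np.float32)
        cfg = ClassificationLossConfig(gamma=2.0, alpha=0.5)
        got = float(focal_loss_t(nn.Tensor(p), t, cfg.gamma, cfg.alpha).data)
        expect = focal_classification_loss(p, t, cfg)
        assert got == pytest.approx(expect, rel=1e-4)


class TestWeightedBCE:
    def test_perfect_prediction_near_zero(self):
        y = np.array([0.0, 1.0, 1.0])
        assert weighted_bce(np.clip(y, 1e-7, 1 - 1e-7), y) < 1e-5

    def test_hand_arithmetic(self):
        assert weighted_bce(np.array([0.5]), np.array([1.0])) == \
            pytest.approx(math.log(2), rel=1e-9)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(47)
        p = rng.uniform(0.1, 0.9, 20)
        y = (rng.random(20) < 0.5).astype(float)
        perm = rng.permutation(20)
        assert weighted_bce(p, y) == pytest.approx(weighted_bce(p[perm], y[perm]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(np.array([0.5, 0.5]), np.array([1.0]))


def _fake_assignment(pos, labels, gt_boxes, strides, soft=None, n_anchors=20):
    from koadet.assigner import Assignment

    pos = np.asarray(pos, dtype=np.int64)
    return Assignment(n_anchors, pos, np.asarray(labels, dtype=np.int64),
                      np.arange(len(pos)), np.asarray(gt_boxes, float),
                      np.asarray(strides, float),
                      np.ones(len(pos)) if soft is None else np.asarray(soft))


class TestTotalLoss:
    def test_perfect_predictions_near_zero(self):
        cfg = LossConfig(soft_targets=False)
        probs = np.full((20, 5), 1e-7, dtype=np.float32)
        probs[[2, 5], [1, 1]] = 1 - 1e-7
        boxes = np.tile(np.array([0, 0, 8, 8], np.float32), (20, 1))
        assignment = _fake_assignment([2, 5], [1, 1],
                                      [[0, 0, 8, 8]] * 2, [8, 8])
        _, _, total = total_loss(nn.Tensor(probs), nn.Tensor(boxes),
                                 assignment, cfg)
        assert float(total.data) < 1e-3

    def test_no_positives_total_equals_cls(self):
        cfg = LossConfig(soft_targets=False)
        probs = np.random.default_rng(0).uniform(0.1, 0.5, (20, 5)).astype(np.float32)
        boxes = np.zeros((20, 4), np.float32)
        assignment = _fake_assignment([], [], np.empty((0, 4)), [])
        cls, reg, total = total_loss(nn.Tensor(probs), nn.Tensor(boxes),
                                     assignment, cfg)
        assert float(reg.data) == 0.0
        assert float(total.data) == pytest.approx(float(cls.data))

    def test_decomposes_into_components(self):
        rng = np.random.default_rng(53)
        cfg = LossConfig(soft_targets=False)
        probs = rng.uniform(0.05, 0.95, (20, 5)).astype(np.float32)
        boxes = np.stack([np.array(random_box(rng)) for _ in range(20)]
                         ).astype(np.float32)
        assignment = _fake_assignment([1, 7, 9], [0, 2, 4],
                                      [random_box(rng) for _ in range(3)],
                                      [8, 16, 32])
        cls, reg, total = total_loss(nn.Tensor(probs), nn.Tensor(boxes),
                                     assignment, cfg)
        assert float(total.data) == pytest.approx(
            float(cls.data) + float(reg.data), rel=1e-6)


def _descend(loss_fn, start: Box, target: Box, lr=0.02, max_iter=3000):
    """Normalized numeric gradient descent on (cx, cy, w, h); returns the
    iteration count to reach IoU >= 0.99 (or max_iter)."""
    p = np.array([(start.x_min + start.x_max) / 2,
                  (start.y_min + start.y_max) / 2,
                  start.width, start.height], dtype=np.float64)
    eps = 1e-4

    def mk(q):
        w, h = max(q[2], 1e-3), max(q[3], 1e-3)
        return Box(q[0] - w / 2, q[1] - h / 2, q[0] + w / 2, q[1] + h / 2)

    for it in range(max_iter):
        if iou(mk(p), target) >= 0.99:
            return it
        grad = np.zeros(4)
        for k in range(4):
            up, dn = p.copy(), p.copy()
            up[k] += eps
            dn[k] -= eps
            grad[k] = (loss_fn(mk(up), target) - loss_fn(mk(dn), target)) / (2 * eps)
        norm = np.linalg.norm(grad)
        if norm < 1e-12:
            break
        p -= lr * grad / norm
    return max_iter


class TestConvergence:
    def test_eiou_descends_at_least_as_fast_as_giou(self):
        """EIoU's direct edge-length penalty should not converge slower than
        GIoU on randomly offset anchors (3-seed median over 20 cases)."""
        medians = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            diffs = []
            for _ in range(20):
                target = Box(0.0, 0.0, 4.0, 4.0)
                cx, cy = rng.uniform(-6, 6, 2)
                w, h = rng.uniform(1.0, 8.0, 2)
                start = Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
                it_e = _descend(lambda p, g: eiou_loss(p, g).total, start, target)
                it_g = _descend(giou_loss, start, target)
                diffs.append(it_g - it_e)
            medians.append(np.median(diffs))
        assert np.median(medians) >= 0
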