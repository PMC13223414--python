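import numpy as np
import pytest

from koadet import nn
from koadet.config import HeadConfig
from koadet.head import TaskAlignedHead


@pytest.fixture()
def head():
    return TaskAlignedHead(HeadConfig(channels=64), seed=1)


def _feat(seed=0, c=64, h=6, w=6):
    rng = np.random.default_rng(seed)
    return nn.Tensor(rng.standard_normal((1, c, h, w)).astype(np.float32))


class TestInteractiveExtractor:
    def test_six_layers_retained(self, head):
        with nn.no_grad():
            feats = head.interactive_extractor(_feat())
        assert len(feats) == 6

    def test_spatial_size_preserved_and_nonnegative(self, head):
        with nn.no_grad():
            feats = head.interactive_extractor(_feat(h=5, w=7))
        for f in feats:
            assert f.shape[2:] == (5, 7)
            assert (f.data >= 0).all()

    def test_indivisible_group_count_rejected(self):
        with pytest.raises(ValueError):
            TaskAlignedHead(HeadConfig(channels=48, gn_groups=32))

    def test_default_profile_has_32_group_norms(self):
        head = TaskAlignedHead(HeadConfig())
        assert len(head.inter_convs) == 6
        assert all(norm.groups == 32 for norm in head.inter_norms)
        assert all(conv.weight.shape[-1] == 3 for conv in head.inter_convs)


class TestLayerAttention:
    def test_zeroed_fc_gives_half(self, head):
        br = head.branches["cls"]
        for layer in (br["fc1"], br["fc2"]):
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        with nn.no_grad():
            inter = head.interactive_extractor(_feat())
            omega = head.layer_attention(inter, "cls")
        assert np.allclose(omega.data, 0.5)

    def test_weights_in_open_unit_interval(self, head):
        with nn.no_grad():
            inter = head.interactive_extractor(_feat(seed=3))
            for task in ("cls", "loc"):
                omega = head.layer_attention(inter, task).numpy()
                assert omega.shape == (1, 6)
                assert np.all(omega > 0) and np.all(omega < 1)

    def test_zero_weight_removes_layer_contribution(self, head, monkeypatch):
        with nn.no_grad():
            inter = head.interactive_extractor(_feat(seed=4))
        fixed = np.ones((1, 6), dtype=np.float32)
        fixed[0, 2] = 0.0
        monkeypatch.setattr(head, "layer_attention",
                            lambda inter, task: nn.Tensor(fixed))
        perturbed = list(inter)
        perturbed[2] = perturbed[2] * 100.0 + 5.0
        with nn.no_grad():
            a = head.task_predict(inter, "cls").numpy()
            b = head.task_predict(perturbed, "cls").numpy()
        assert np.allclose(a, b, atol=1e-5)


class TestTaskPredict:
    def test_classification_scores_in_unit_interval(self, head):
        with nn.no_grad():
            out = head.forward_level(_feat(seed=5), 0)
        s = out.raw_scores.numpy()
        assert np.all(s > 0) and np.all(s < 1)

    def test_five_grade_channels(self, head):
        with nn.no_grad():
            out = head.forward_level(_feat(seed=5), 0)
        assert out.scores.shape[1] == 5

    def test_distances_nonnegative(self, head):
        with nn.no_grad():
            out = head.forward_level(_feat(seed=6), 0)
        assert (out.distances.numpy() >= 0).all()


class TestAlignmentMaps:
    def test_m_in_unit_interval_o_eight_channels(self, head):
        with nn.no_grad():
            inter = head.interactive_extractor(_feat(seed=7))
            m, o = head.alignment_maps(inter)
        assert m.shape[1] == 1
        assert np.all(m.data > 0) and np.all(m.data < 1)
        assert o.shape[1] == 8

    def test_align_classification_identities(self, head):
        rng = np.random.default_rng(8)
        p = nn.Tensor(rng.uniform(0.1, 0.9, (1, 5, 4, 4)).astype(np.float32))
        m_eq = nn.Tensor(p.data.copy())
        assert np.allclose(head.align_classification(p, m_eq).data, p.data,
                           atol=1e-6)
        ones = nn.Tensor(np.ones((1, 1, 4, 4), np.float32))
        aligned = head.align_classification(p, ones).numpy()
        assert np.all(aligned >= p.data - 1e-7)  # sqrt(P) >= P on [0,1]

    def test_geometric_mean_betweenness(self, head):
        rng = np.random.default_rng(9)
        p = nn.Tensor(rng.uniform(0.01, 0.99, (1, 5, 6, 6)).astype(np.float32))
        m = nn.Tensor(rng.uniform(0.01, 0.99, (1, 1, 6, 6)).astype(np.float32))
        a = head.align_classification(p, m).numpy()
        lo = np.minimum(p.data, m.data)
        hi = np.maximum(p.data, m.data)
        assert np.all(a >= lo - 1e-6) and np.all(a <= hi + 1e-6)


class TestAlignLocalization:
    def test_zero_offsets_are_identity(self):
        rng = np.random.default_rng(10)
        b = nn.Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        o = nn.Tensor(np.zeros((1, 8, 5, 5), np.float32))
        out = nn.boundary_sample(b, o)
        assert np.allclose(out.data, b.data, atol=1e-7)

    def test_integer_offsets_match_direct_indexing(self):
        rng = np.random.default_rng(11)
        b = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        o = np.zeros((1, 8, 5, 5), np.float32)
        o[:, 0::2] = rng.integers(-2, 3, (1, 4, 5, 5))
        o[:, 1::2] = rng.integers(-2, 3, (1, 4, 5, 5))
        out = nn.boundary_sample(nn.Tensor(b), nn.Tensor(o)).numpy()
        ii, jj = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        for c in range(4):
            si = np.clip(ii + o[0, 2 * c].astype(int), 0, 4)
            sj = np.clip(jj + o[0, 2 * c + 1].astype(int), 0, 4)
            assert np.allclose(out[0, c], b[0, c][si, sj], atol=1e-6)

    def test_fractional_offset_interpolates_ramp(self):
        # two-cell ramp along rows: offset (0.5, 0) samples the midpoint
        b = np.zeros((1, 4, 2, 1), np.float32)
        b[0, 0, :, 0] = [2.0, 6.0]
        o = np.zeros((1, 8, 2, 1), np.float32)
        o[0, 0, 0, 0] = 0.5
        out = nn.boundary_sample(nn.Tensor(b), nn.Tensor(o)).numpy()
        assert out[0, 0, 0, 0] == pytest.approx(4.0)

    def test_boundary_channels_independent(self, head):
        with nn.no_grad():
            feat = _feat(seed=12)
            out = head.forward_level(feat, 0)
            base = out.distances.numpy()

            inter = head.interactive_extractor(feat)
            dist_map = head._distances(head.task_predict(inter, "loc"), 0)
            _, o = head.alignment_maps(inter)
            o_pert = o.numpy()
            o_pert[:, 2:4] += 0.8  # boundary c=1 (top) only
            d2 = nn.boundary_sample(dist_map, nn.Tensor(o_pert)).numpy()
        d2 = np.transpose(d2, (0, 2, 3, 1)).reshape(-1, 4)
        changed = [not np.allclose(d2[:, c], base[:, c], atol=1e-6)
                   for c in range(4)]
        assert changed[1]
        assert not any(changed[c] for c in (0, 2, 3))


class TestHeadForward:
    def test_deterministic_in_eval_mode(self, head):
        head.eval()
        pyramid = [_feat(seed=20 + i, h=max(6 >> i, 1), w=max(6 >> i, 1))
                   for i in range(5)]
        with nn.no_grad():
            a = head(pyramid)
            b = head(pyramid)
        for x, y in zip(a, b):
            assert np.array_equal(x.scores.data, y.scores.data)
            assert np.array_equal(x.boxes.data, y.boxes.data)

    def test_disabling_alignment_reduces_to_plain_head(self):
        aligned = TaskAlignedHead(HeadConfig(channels=64, align=True), seed=2)
        plain = TaskAlignedHead(HeadConfig(channels=64, align=False), seed=2)
        plain.load_state_dict(aligned.state_dict())
        with nn.no_grad():
            a = plain.forward_level(_feat(seed=30), 0)
        assert np.allclose(a.scores.data, a.raw_scores.data, atol=1e-7)
        assert np.allclose(a.spatial_prob.data, 1.0)
        assert np.allclose(a.offsets.data, 0.0)

    def test_decoded_boxes_contain_anchor_points(self, head):
        with nn.no_grad():
            out = head.forward_level(_feat(seed=31), 0)
        boxes = out.boxes.numpy()
        assert np.all(boxes[:, 0] <= out.anchors[:, 0] + 1e-5)
        assert np.all(boxes[:, 2] >= out.anchors[:, 0] - 1e-5)
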