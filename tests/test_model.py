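"""Architecture structure: parameter/FLOP accounting, head geometry,
pyramid-pooling properties and prediction decoding."""

from __future__ import annotations

import numpy as np
import pytest

from lsnet import nn
from lsnet.boxes import BBox, Detection
from lsnet.decode import decode_predictions, nms
from lsnet.model import (LSNET_ANCHORS, YOLOV7_ANCHORS, ModelConfig, build_graph,
                         build_model, count_parameters, count_flops, summarize,
                         _node_shapes_params_flops)
from lsnet.nn import Tensor, no_grad
from lsnet.nn import functional as F


def cfg_for(variant: str, nc: int = 80, **kw) -> ModelConfig:
    anchors = {
        "lsnet": LSNET_ANCHORS, "minus_p5_p2": LSNET_ANCHORS,
        "yolov7": YOLOV7_ANCHORS, "minus_p5": YOLOV7_ANCHORS[:2],
        "plus_p2": (LSNET_ANCHORS[0],) + YOLOV7_ANCHORS,
    }[variant]
    return ModelConfig(variant=variant, num_classes=nc, anchors=anchors, **kw)


class TestParameterCounts:
    """The ablation chain's parameter column, at the 80-class training-form
    summary convention the published table uses."""

    EXPECTED = {
        "yolov7": 37_620_125,
        "minus_p5": 26_337_950,
        "minus_p5_p2": 26_919_709,
        "lsnet": 26_251_037,
        "plus_p2": 38_201_884,
    }

    @pytest.mark.parametrize("variant", sorted(EXPECTED))
    def test_frozen_reference_counts(self, variant):
        assert summarize(cfg_for(variant))["parameters"] == self.EXPECTED[variant]

    def test_ablation_ordering_strict(self):
        p = {v: summarize(cfg_for(v))["parameters"] for v in self.EXPECTED}
        assert p["yolov7"] > p["minus_p5_p2"] > p["lsnet"]
        assert p["minus_p5"] < p["minus_p5_p2"]
        assert p["plus_p2"] > p["yolov7"]

    def test_static_count_matches_instantiated(self, tiny_model):
        assert count_parameters(tiny_model) == \
            summarize(tiny_model.cfg)["parameters"]

    def test_count_is_pure_function_of_config(self):
        cfg = cfg_for("lsnet", nc=3)
        assert summarize(cfg)["parameters"] == summarize(cfg)["parameters"]
        a = count_parameters(build_model(ModelConfig(width_multiple=0.125, seed=1)))
        b = count_parameters(build_model(ModelConfig(width_multiple=0.125, seed=2)))
        assert a == b

    def test_single_cbs_block_hand_count(self):
        conv = nn.Conv2d(3, 32, 3)
        bn = nn.BatchNorm2d(32)
        total = sum(p.data.size for p in conv.parameters()) + \
            sum(p.data.size for p in bn.parameters())
        assert total == 3 * 32 * 9 + 2 * 32 == 928

    def test_deploy_rep_is_smaller_than_training_form(self):
        train = summarize(cfg_for("lsnet", rep_mode="train"))["parameters"]
        deploy = summarize(cfg_for("lsnet", rep_mode="deploy"))["parameters"]
        assert deploy < train


class TestFlops:
    def test_quadratic_scaling_with_input(self):
        cfg = cfg_for("lsnet")
        assert count_flops(cfg, 320) / count_flops(cfg, 640) == pytest.approx(0.25)

    def test_single_conv_closed_form(self):
        nodes = [{"op": "conv", "from": [-1], "c2": 8, "k": 3, "s": 1, "g": 1,
                  "d": 1, "act": True, "bn": True, "bias": False}]
        _, params, flops = _node_shapes_params_flops(nodes, 16)
        assert flops == 2 * 9 * 3 * 8 * 16 * 16
        assert params == 3 * 8 * 9 + 16

    def test_lkaspp_cheaper_than_sppcspc(self):
        lk = summarize(cfg_for("lsnet"))
        sp = summarize(cfg_for("minus_p5_p2"))
        assert lk["parameters"] < sp["parameters"]
        assert lk["gflops"] < sp["gflops"]


class TestHeadGeometry:
    def test_grid_sizes_at_640(self):
        s = summarize(cfg_for("lsnet", nc=3), 640)
        assert s["head_grids"] == [160, 80, 40]
        assert s["strides"] == [4, 8, 16]

    def test_grid_sizes_at_320(self):
        assert summarize(cfg_for("lsnet", nc=3), 320)["head_grids"] == [80, 40, 20]

    def test_head_channels_for_three_classes(self):
        assert summarize(cfg_for("lsnet", nc=3))["head_channels"] == [24, 24, 24]

    def test_no_stride32_prediction_head(self):
        for variant in ("lsnet", "minus_p5_p2"):
            assert 32 not in cfg_for(variant).strides

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            summarize(cfg_for("lsnet"), 600)
        with pytest.raises(ValueError):
            ModelConfig(input_size=600)

    def test_anchor_head_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="yolov7", anchors=LSNET_ANCHORS[:2])

    def test_real_forward_shapes_and_determinism(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(1, 3, 160, 160)).astype(np.float32)
        tiny_model.eval()
        with no_grad():
            a = tiny_model(x)
            b = tiny_model(x)
        assert [o.shape[2] for o in a] == [40, 20, 10]
        assert all(np.array_equal(p.data, q.data) for p, q in zip(a, b))


class TestLKASPP:
    def find_gate(self, model):
        """Locate the attention gate: the 'mul' node and its two inputs."""
        for idx, node in enumerate(model.graph):
            if node["op"] == "mul":
                fused, attn = node["from"]
                return idx, fused, attn
        raise AssertionError("no gating node in the graph")

    def test_all_ones_attention_is_identity(self, tiny_model):
        """With the attention map forced to 1 the gate passes the pooled
        CSP path through unchanged."""
        mul_idx, fused_idx, attn_idx = self.find_gate(tiny_model)
        conv = tiny_model.blocks[attn_idx].layers[0]
        saved_w, saved_b = conv.weight.data.copy(), conv.bias.data.copy()
        try:
            conv.weight.data = np.zeros_like(conv.weight.data)
            conv.bias.data = np.ones_like(conv.bias.data)
            x = np.random.default_rng(1).normal(size=(1, 3, 160, 160)).astype(np.float32)
            tiny_model.eval()
            with no_grad():
                feats = tiny_model.forward_features(x, [mul_idx, fused_idx])
            np.testing.assert_allclose(feats[mul_idx].data, feats[fused_idx].data,
                                       rtol=1e-6)
        finally:
            conv.weight.data, conv.bias.data = saved_w, saved_b

    def test_sequential_pool_receptive_field(self):
        """Three 7x7 stride-1 pools spread an impulse to 19x19, beyond the
        13x13 footprint of the largest parallel pool they replace."""
        x = np.full((1, 1, 41, 41), -1.0)
        x[0, 0, 20, 20] = 1.0
        t = Tensor(x)
        for _ in range(3):
            t = F.max_pool2d(t, 7, 1, 3)
        rows = np.flatnonzero((t.data[0, 0] == 1.0).any(axis=1))
        assert rows[-1] - rows[0] + 1 == 19
        single = F.max_pool2d(Tensor(x), 13, 1, 6)
        rows13 = np.flatnonzero((single.data[0, 0] == 1.0).any(axis=1))
        assert rows13[-1] - rows13[0] + 1 == 13
        assert 19 >= 13

    def test_output_spatial_and_channel_contract(self):
        """The pyramid block maps the stride-32 feature to the same spatial
        size with the neck's expected channel count."""
        for variant in ("lsnet", "minus_p5_p2"):
            nodes, _ = build_graph(cfg_for(variant))
            shapes, _, _ = _node_shapes_params_flops(nodes, 640)
            # the deepest backbone feature is 1024ch at 20x20; the pyramid
            # output is the first subsequent 512ch 20x20 map
            assert (1024, 20, 20) in shapes
            assert (512, 20, 20) in shapes


class TestDecode:
    STRIDES = (4, 8, 16)
    ANCHORS = LSNET_ANCHORS

    def outputs(self, size=64, nc=3, fill=0.0):
        outs = []
        for s in self.STRIDES:
            g = size // s
            outs.append(np.full((1, 3 * (5 + nc), g, g), fill, dtype=np.float32))
        return outs

    def test_zero_logits_give_no_detections(self):
        dets = decode_predictions(self.outputs(), self.ANCHORS, self.STRIDES, 3,
                                  conf_thresh=0.25)
        assert dets == [[]]

    def test_single_forced_cell(self):
        outs = self.outputs()
        no = 8
        view = outs[0].reshape(1, 3, no, 16, 16)
        view[0, 1, 4, 5, 7] = 8.0    # objectness at cell (row 5, col 7)
        view[0, 1, 5, 5, 7] = 8.0    # class 0
        dets = decode_predictions(outs, self.ANCHORS, self.STRIDES, 3,
                                  conf_thresh=0.25)[0]
        assert len(dets) == 1
        d = dets[0]
        assert d.class_id == 0
        # zero offset logits decode to the cell centre at anchor size
        assert d.box.cx == pytest.approx((0.5 + 7) * 4)
        assert d.box.cy == pytest.approx((0.5 + 5) * 4)
        assert (d.box.w, d.box.h) == (pytest.approx(8.0), pytest.approx(9.0))

    def test_nms_deduplicates_identical_boxes(self):
        boxes = np.array([[10, 10, 8, 8], [10, 10, 8, 8], [40, 40, 8, 8]], float)
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5)
        assert sorted(keep.tolist()) == [0, 2]

    def test_merge_of_empty_outputs(self):
        assert decode_predictions([], (), (), 3) == []
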