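"""Training harness: schedule, assignment, loss assembly, checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

from lsnet import losses as L
from lsnet.model import ModelConfig, build_model
from lsnet.nn import Tensor, no_grad
from lsnet.train import (TrainConfig, assemble_loss, build_targets,
                         load_checkpoint, lr_schedule, save_checkpoint,
                         train_detector)


class TestSchedule:
    CFG = TrainConfig(epochs=300)

    def test_published_endpoints(self):
        assert lr_schedule(0, self.CFG) == pytest.approx(0.01)
        assert lr_schedule(300, self.CFG) == pytest.approx(0.0001)

    def test_cosine_midpoint(self):
        assert lr_schedule(150, self.CFG) == pytest.approx((0.01 + 0.0001) / 2)

    def test_monotone_nonincreasing(self):
        lrs = [lr_schedule(e, self.CFG) for e in range(301)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, self.CFG)
        with pytest.raises(ValueError):
            lr_schedule(301, self.CFG)


class TestTargetAssignment:
    def test_centre_cell_and_ratio_gate(self, tiny_model):
        grids = [(40, 40), (20, 20), (10, 10)]
        # one 20x20 target at (52, 36) in a 160 input
        targets = np.array([[0, 1, 52.0, 36.0, 20.0, 20.0]])
        per_head = build_targets(targets, tiny_model, grids, ratio_thresh=4.0,
                                 neighbor_cells=False)
        head0 = per_head[0]
        assert head0["img"].size >= 1
        assert (head0["gi"] == 13).all() and (head0["gj"] == 9).all()
        oversize = np.array([[0, 1, 52.0, 36.0, 500.0, 500.0]])
        none_assigned = build_targets(oversize, tiny_model, grids, 4.0)
        assert all(a["img"].size == 0 for a in none_assigned)

    def test_best_mode_single_positive(self, tiny_model):
        grids = [(40, 40), (20, 20), (10, 10)]
        targets = np.array([[0, 0, 80.0, 80.0, 20.0, 20.0]])
        per_head = build_targets(targets, tiny_model, grids,
                                 assign_mode="best", neighbor_cells=False)
        assert sum(a["img"].size for a in per_head) == 1

    def test_neighbor_cells_add_two(self, tiny_model):
        grids = [(40, 40), (20, 20), (10, 10)]
        targets = np.array([[0, 0, 80.0, 80.0, 20.0, 20.0]])
        with_nb = build_targets(targets, tiny_model, grids,
                                assign_mode="best", neighbor_cells=True)
        assert sum(a["img"].size for a in with_nb) == 3

    def test_empty_targets(self, tiny_model):
        per_head = build_targets(np.zeros((0, 6)), tiny_model,
                                 [(40, 40), (20, 20), (10, 10)])
        assert all(a["img"].size == 0 for a in per_head)


class TestLossAssembly:
    def _forward(self, tiny_model, small_scenes, n=2):
        batch = np.stack([small_scenes[i][0] for i in range(n)])
        tgts = [np.concatenate([np.full((small_scenes[i][1].shape[0], 1), i),
                                small_scenes[i][1]], axis=1) for i in range(n)]
        with no_grad():
            outs = tiny_model(Tensor(batch))
        return outs, np.concatenate(tgts)

    def test_hand_summed_single_target(self, tiny_model):
        """One target, centre-cell assignment: the total equals the three
        hand-computed terms."""
        cfg = TrainConfig(input_size=160, neighbor_cells=False,
                          assign_mode="best", box_loss="ciou",
                          lambda_box=0.05, lambda_obj=1.0, lambda_cls=0.5)
        rng = np.random.default_rng(0)
        outs = [Tensor(rng.normal(0, 0.5, (1, 24, g, g)).astype(np.float32))
                for g in (40, 20, 10)]
        targets = np.array([[0, 1, 80.0, 80.0, 20.0, 20.0]])
        parts = assemble_loss(outs, targets, tiny_model, cfg)
        assigned = build_targets(targets, tiny_model,
                                 [(40, 40), (20, 20), (10, 10)],
                                 assign_mode="best", neighbor_cells=False)
        (head,) = [i for i, a in enumerate(assigned) if a["img"].size]
        asg = assigned[head]
        raw = outs[head].data.reshape(1, 3, 8, *outs[head].shape[2:])
        p = raw[0, asg["anchor"][0], :, asg["gj"][0], asg["gi"][0]]
        sig = 1 / (1 + np.exp(-p))
        stride = tiny_model.strides[head]
        pred = np.array([(sig[0] * 2 - 0.5 + asg["gi"][0]) * stride,
                         (sig[1] * 2 - 0.5 + asg["gj"][0]) * stride,
                         (sig[2] * 2) ** 2 * asg["anchor_wh"][0, 0],
                         (sig[3] * 2) ** 2 * asg["anchor_wh"][0, 1]])
        box_hand = float(L.ciou_loss(pred, asg["box"][0]))
        assert parts["box"] == pytest.approx(box_hand, rel=1e-5)
        total_hand = 0.05 * parts["box"] + 1.0 * parts["obj"] + 0.5 * parts["cls"]
        assert float(parts["total"].data) == pytest.approx(total_hand, rel=1e-6)

    def test_box_term_isolation_between_loss_choices(self, tiny_model, small_scenes):
        """Switching ciou -> wiou_v3 on a fixed batch changes only the box
        component."""
        outs, targets = self._forward(tiny_model, small_scenes)
        state = L.RunningIoUState()
        L.update_running_mean(state, 0.5, L.FocusingConfig())
        base = dict(input_size=160)
        a = assemble_loss(outs, targets, tiny_model,
                          TrainConfig(box_loss="ciou", **base), state)
        b = assemble_loss(outs, targets, tiny_model,
                          TrainConfig(box_loss="wiou_v3", **base), state)
        assert a["obj"] == pytest.approx(b["obj"], rel=1e-7)
        assert a["cls"] == pytest.approx(b["cls"], rel=1e-7)
        assert a["box"] != pytest.approx(b["box"], rel=1e-3)

    def test_no_targets_still_supervises_objectness(self, tiny_model, small_scenes):
        outs, _ = self._forward(tiny_model, small_scenes, n=1)
        parts = assemble_loss(outs, np.zeros((0, 6)), tiny_model,
                              TrainConfig(input_size=160))
        assert parts["box"] == 0.0 and parts["cls"] == 0.0
        assert parts["obj"] > 0
        assert parts["mean_liou"] is None

    def test_loss_finite_on_random_batches(self, tiny_model):
        """No NaN/Inf across random inputs and random targets."""
        rng = np.random.default_rng(9)
        cfg = TrainConfig(input_size=160, box_loss="wiou_v3")
        state = L.RunningIoUState()
        L.update_running_mean(state, 0.5, cfg.focusing)
        for _ in range(10):
            outs = [Tensor(rng.normal(0, 3, (1, 24, g, g)).astype(np.float32))
                    for g in (40, 20, 10)]
            m = rng.integers(0, 12)
            targets = np.column_stack([
                np.zeros(m), rng.integers(0, 3, m),
                rng.uniform(5, 155, m), rng.uniform(5, 155, m),
                rng.uniform(3, 60, m), rng.uniform(3, 60, m)])
            parts = assemble_loss(outs, targets, tiny_model, cfg, state)
            assert np.isfinite(parts["total"].data)

    def test_wiou_v3_pairwise_finiteness_bulk(self):
        """The box loss itself stays finite over 1,000 random pairs."""
        rng = np.random.default_rng(10)
        cfg = L.FocusingConfig(warmup_steps=0)
        state = L.RunningIoUState()
        L.update_running_mean(state, 0.4, cfg)
        p = np.column_stack([rng.uniform(-500, 500, 1000), rng.uniform(-500, 500, 1000),
                             rng.uniform(1e-3, 600, 1000), rng.uniform(1e-3, 600, 1000)])
        g = np.column_stack([rng.uniform(-500, 500, 1000), rng.uniform(-500, 500, 1000),
                             rng.uniform(1e-3, 600, 1000), rng.uniform(1e-3, 600, 1000)])
        out = L.wiou_v3_loss(p, g, state, cfg)
        assert np.isfinite(out).all() and (out >= 0).all()


class TestLoopAndCheckpoints:
    def make_samples(self, small_scenes, n=2):
        return small_scenes[:n]

    def test_two_epoch_determinism(self, small_anchors, small_scenes):
        """Two runs from the same seed produce identical loss traces."""
        def run():
            cfg = ModelConfig(variant="lsnet", num_classes=3, width_multiple=0.125,
                              input_size=160, anchors=small_anchors, seed=0)
            model = build_model(cfg)
            tcfg = TrainConfig(epochs=2, batch_size=2, input_size=160,
                               lr_init=0.005, seed=3)
            return train_detector(model, self.make_samples(small_scenes),
                                  tcfg)["history"]

        h1, h2 = run(), run()
        assert h1 == h2

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            train_detector(tiny_model, [], TrainConfig(epochs=1))

    def test_checkpoint_roundtrip(self, small_anchors, tmp_path):
        cfg = ModelConfig(variant="lsnet", num_classes=3, width_multiple=0.125,
                          input_size=160, anchors=small_anchors, seed=1)
        model = build_model(cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, epoch=7)
        clone = build_model(ModelConfig(variant="lsnet", num_classes=3,
                                        width_multiple=0.125, input_size=160,
                                        anchors=small_anchors, seed=2))
        before = [p.data.copy() for p in clone.parameters()]
        meta = load_checkpoint(path, clone)
        assert meta["epoch"] == 7
        after = list(clone.parameters())
        assert any(not np.array_equal(b, a.data) for b, a in zip(before, after))
        for p, q in zip(model.parameters(), clone.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        x = np.random.default_rng(0).normal(size=(1, 3, 160, 160)).astype(np.float32)
        model.eval(), clone.eval()
        with no_grad():
            a, b = model(x), clone(x)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u.data, v.data)
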