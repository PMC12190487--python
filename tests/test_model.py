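"""Detector assembly, target assignment, losses, decoding and NMS."""

import numpy as np
import pytest

from aquadet.autodiff import SGD, Tensor
from aquadet.boxes import BoundingBox, WiouState
from aquadet.model import (ArchitectureConfig, Detection, assign_targets,
                           build_model, decode_grid, detection_loss, encode_box,
                           load_checkpoint, nms, predict, save_checkpoint,
                           training_step)
from aquadet.scenes import GroundTruthScene, SceneSpec, generate_scene

TINY = dict(input_size=64, width_mult=0.125)


def tiny_cfg(**kw):
    return ArchitectureConfig(**{**TINY, **kw})


def tiny_scenes(n, size=64, seed0=100):
    return [generate_scene(SceneSpec("deformation", size, 2, seed=seed0 + i))
            for i in range(n)]


class TestArchitecture:
    def test_grid_sizes_follow_strides(self):
        for size, small in [(64, True), (64, False), (128, True)]:
            cfg = tiny_cfg(input_size=size, small_head=small)
            model = build_model(cfg, seed=0)
            outs = model(Tensor(np.zeros((1, 3, size, size))))
            assert [o.shape[2] for o in outs] == [size // s for s in cfg.strides]
            assert all(o.shape[1] == 5 + cfg.num_classes for o in outs)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(input_size=100, small_head=True)

    def test_parameter_count_grows_with_each_toggle(self):
        base = build_model(tiny_cfg(use_dcn=False, attention="none",
                                    small_head=False), 0).num_parameters()
        plus_dcn = build_model(tiny_cfg(use_dcn=True, attention="none",
                                        small_head=False), 0).num_parameters()
        plus_att = build_model(tiny_cfg(use_dcn=False, attention="dpse",
                                        small_head=False), 0).num_parameters()
        plus_head = build_model(tiny_cfg(use_dcn=False, attention="none",
                                         small_head=True), 0).num_parameters()
        assert plus_dcn > base and plus_att > base and plus_head > base

    def test_dcn_swap_preserves_initial_forward(self, rng):
        """With zero-initialized offset branches, replacing the deep block's
        standard convolutions by deformable ones leaves the first forward
        pass unchanged."""
        plain = build_model(tiny_cfg(use_dcn=False, attention="none"), seed=3)
        deform = build_model(tiny_cfg(use_dcn=True, attention="none"), seed=3)
        state = plain.state_dict()
        dstate = deform.state_dict()
        mapped = {}
        for key, val in dstate.items():
            if key in state:
                mapped[key] = state[key]
            elif key.endswith(".weight") and \
                    key[:-7] + ".conv.weight" in state:
                mapped[key] = state[key[:-7] + ".conv.weight"]
            else:
                mapped[key] = val  # offset branches stay zero
        deform.load_state_dict(mapped)
        x = Tensor(rng.random((1, 3, 64, 64)))
        for a, b in zip(plain(x), deform(x)):
            assert np.abs(a.data - b.data).max() < 1e-4

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_model(tiny_cfg(), seed=1)
        save_checkpoint(model, tmp_path / "m.npz")
        clone = build_model(tiny_cfg(), seed=99)
        load_checkpoint(clone, tmp_path / "m.npz")
        x = Tensor(rng.random((1, 3, 64, 64)))
        model.eval(), clone.eval()
        for a, b in zip(model(x), clone(x)):
            assert np.array_equal(a.data, b.data)


class TestAssignTargets:
    strides4 = [4, 8, 16, 32]
    grids4 = [(40, 40), (20, 20), (10, 10), (5, 5)]

    def test_size_windows(self):
        # stride s supervises boxes with max side in [s, 8s]; a box can be
        # positive at several scales, tiny boxes fall back to the finest grid
        table = [(6, {0}), (4, {0}), (10, {0, 1}), (20, {0, 1, 2}),
                 (100, {2, 3}), (2, {0}), (40, {1, 2, 3})]
        for side, levels in table:
            asg = assign_targets([BoundingBox(80, 80, side, side)],
                                 self.strides4, self.grids4)
            got = {k for k in range(4) if len(asg[k]["rows"])}
            assert got == levels, f"side {side}: {got} != {levels}"

    def test_small_box_fallback_without_small_head(self):
        asg = assign_targets([BoundingBox(80, 80, 6, 6)], [8, 16, 32],
                             [(20, 20), (10, 10), (5, 5)])
        assert len(asg[0]["rows"]) >= 1  # finest available grid takes it

    def test_large_box_positive_on_stride16_center_cell(self):
        # a 100 px target is detectable from stride 16 upward; its center
        # cell on the 10x10 grid is (5, 5) for a center at (80, 80)
        asg = assign_targets([BoundingBox(80, 80, 100, 100)],
                             self.strides4, self.grids4)
        assert (5, 5) in set(zip(asg[2]["rows"], asg[2]["cols"]))
        assert (2, 2) in set(zip(asg[3]["rows"], asg[3]["cols"]))

    def test_every_gt_gets_a_positive_cell(self, rng):
        for _ in range(50):
            boxes = [BoundingBox(rng.uniform(5, 155), rng.uniform(5, 155),
                                 rng.uniform(3, 80), rng.uniform(3, 80))
                     for _ in range(4)]
            asg = assign_targets(boxes, self.strides4, self.grids4)
            assert sum(len(d["rows"]) for d in asg) >= len(boxes)


class TestLosses:
    def test_encode_decode_roundtrip(self):
        box = BoundingBox(37.3, 52.1, 9.4, 17.8)
        tx, ty, tw, th = encode_box(box, row=6, col=4, stride=8)
        sig = lambda v: 1 / (1 + np.exp(-v))
        cx = (4 + 0.5 + 4 * sig(tx) - 2) * 8
        w = (2 * sig(tw)) ** 2 * 2 * 8
        assert cx == pytest.approx(box.cx, abs=1e-9)
        assert w == pytest.approx(box.w, abs=1e-9)

    def test_box_loss_zero_when_predictions_encode_targets(self):
        cfg = tiny_cfg(box_loss="ciou")
        scene = generate_scene(SceneSpec("deformation", 64, 2, seed=5))
        grids = [(64 // s, 64 // s) for s in cfg.strides]
        asg = assign_targets(scene.boxes, cfg.strides, grids)
        outputs = []
        for lvl, (H, W) in enumerate(grids):
            raw = np.zeros((1, 5 + cfg.num_classes, H, W))
            d = asg[lvl]
            for r, c, tb in zip(d["rows"], d["cols"], d["boxes"]):
                raw[0, 0:4, r, c] = encode_box(BoundingBox(*tb), r, c,
                                               cfg.strides[lvl])
            outputs.append(Tensor(raw))
        _, comps, _ = detection_loss(outputs, [scene], cfg)
        assert comps.box_loss == pytest.approx(0.0, abs=1e-9)
        assert comps.total == pytest.approx(
            comps.box_weight * comps.box_loss + comps.cls_weight * comps.cls_loss)

    def test_empty_scene_has_no_box_loss(self):
        cfg = tiny_cfg()
        scene = GroundTruthScene(image=np.zeros((64, 64, 3), np.uint8),
                                 boxes=[], scene_type="deformation")
        model = build_model(cfg, 0)
        outputs = model(Tensor(np.zeros((1, 3, 64, 64))))
        _, comps, _ = detection_loss(outputs, [scene], cfg)
        assert comps.box_loss == 0.0
        assert comps.cls_loss > 0.0  # negatives still pay objectness loss

    def test_training_step_is_deterministic(self):
        scenes = tiny_scenes(4)

        def run():
            model = build_model(tiny_cfg(box_loss="wiou"), seed=7)
            opt = SGD(model.parameters(), lr=0.01, momentum=0.9)
            state = WiouState()
            vals = []
            for _ in range(3):
                comps, state = training_step(model, scenes, state, opt)
                vals.append(comps.total)
            return vals

        a, b = run(), run()
        assert np.allclose(a, b, atol=1e-6)
        assert np.all(np.isfinite(a))

    def test_wiou_state_updates_during_training(self):
        scenes = tiny_scenes(2)
        model = build_model(tiny_cfg(box_loss="wiou"), seed=1)
        state = WiouState()
        _, new_state = training_step(model, scenes, state)
        assert new_state.mean_iou_loss != state.mean_iou_loss

    def test_nan_weights_raise_diagnostic_error(self):
        scenes = tiny_scenes(1)
        model = build_model(tiny_cfg(), seed=0)
        model.stem.conv.weight.data[:] = np.nan
        with pytest.raises(FloatingPointError):
            training_step(model, scenes)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            training_step(build_model(tiny_cfg(), 0), [])


class TestPredict:
    def test_nms_deduplicates_identical_boxes(self):
        b = BoundingBox(10, 10, 6, 6)
        kept = nms([Detection(b, 0.9), Detection(b, 0.8)], iou_threshold=0.5)
        assert len(kept) == 1 and kept[0].score == 0.9

    def test_nms_keeps_separate_objects_and_classes(self):
        kept = nms([Detection(BoundingBox(10, 10, 6, 6), 0.9),
                    Detection(BoundingBox(40, 40, 6, 6), 0.8),
                    Detection(BoundingBox(10, 10, 6, 6), 0.7, class_id=1)], 0.5)
        assert len(kept) == 3

    def test_decode_grid_matches_manual_oracle(self, rng):
        raw = rng.normal(size=(6, 4, 4))
        boxes, scores = decode_grid(raw, stride=8)
        sig = lambda v: 1 / (1 + np.exp(-v))
        for i in range(4):
            for j in range(4):
                k = i * 4 + j
                assert boxes[k, 0] == pytest.approx(
                    (j + 0.5 + 4 * sig(raw[0, i, j]) - 2) * 8)
                assert boxes[k, 2] == pytest.approx(
                    (2 * sig(raw[2, i, j])) ** 2 * 16)
                assert scores[k, 0] == pytest.approx(
                    sig(raw[4, i, j]) * sig(raw[5, i, j]))

    def test_all_scores_below_threshold_gives_empty(self):
        model = build_model(tiny_cfg(), 0)
        img = np.zeros((64, 64, 3), np.uint8)
        assert predict(model, img, conf_threshold=0.999999) == []

    def test_predictions_clipped_and_deterministic(self, rng):
        model = build_model(tiny_cfg(), 0)
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        d1 = predict(model, img, conf_threshold=0.01)
        d2 = predict(model, img, conf_threshold=0.01)
        assert d1 == d2
        for d in d1:
            assert d.box.x1 >= 0 and d.box.x2 <= 64
            assert 0 <= d.score <= 1
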