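"""Box geometry and the IOU / CIOU / Wise-IOU regression losses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquadet.autodiff import Tensor
from aquadet.boxes import (BoundingBox, WiouState, batched_ciou_loss,
                           batched_iou, batched_wiou_loss, ciou_loss,
                           enclosure, iou, read_yolo_labels, update_wiou_state,
                           wiou_loss, write_yolo_labels)
from conftest import finite_difference, random_box

box_strategy = st.builds(
    BoundingBox,
    cx=st.floats(-50, 50), cy=st.floats(-50, 50),
    w=st.floats(0.1, 60), h=st.floats(0.1, 60))


def rasterized_iou(a: BoundingBox, b: BoundingBox, n: int = 400) -> float:
    """Independent IOU oracle: count cells of a fine grid inside each box."""
    x_lo = min(a.x1, b.x1) - 1
    x_hi = max(a.x2, b.x2) + 1
    y_lo = min(a.y1, b.y1) - 1
    y_hi = max(a.y2, b.y2) + 1
    xs = np.linspace(x_lo, x_hi, n)
    ys = np.linspace(y_lo, y_hi, n)
    xx, yy = np.meshgrid(xs, ys)
    in_a = (xx >= a.x1) & (xx <= a.x2) & (yy >= a.y1) & (yy <= a.y2)
    in_b = (xx >= b.x1) & (xx <= b.x2) & (yy >= b.y1) & (yy <= b.y2)
    return (in_a & in_b).sum() / (in_a | in_b).sum()


def ciou_oracle(p: BoundingBox, t: BoundingBox) -> float:
    """Term-by-term reference: IOU loss + center distance + aspect penalty."""
    ix = max(0.0, min(p.x2, t.x2) - max(p.x1, t.x1))
    iy = max(0.0, min(p.y2, t.y2) - max(p.y1, t.y1))
    i = ix * iy / (p.area + t.area - ix * iy)
    rho2 = (p.cx - t.cx) ** 2 + (p.cy - t.cy) ** 2
    cw = max(p.x2, t.x2) - min(p.x1, t.x1)
    ch = max(p.y2, t.y2) - min(p.y1, t.y1)
    v = 4 / math.pi ** 2 * (math.atan(t.w / t.h) - math.atan(p.w / p.h)) ** 2
    alpha = 0.0 if v == 0 else v / (1 - i + v + 1e-12)
    return 1 - i + rho2 / (cw ** 2 + ch ** 2 + 1e-12) + alpha * v


def wiou_oracle(p: BoundingBox, t: BoundingBox, state: WiouState) -> float:
    """Symbol-by-symbol reference for the Wise-IOU loss."""
    ix = max(0.0, min(p.x2, t.x2) - max(p.x1, t.x1))
    iy = max(0.0, min(p.y2, t.y2) - max(p.y1, t.y1))
    liou = 1 - ix * iy / (p.area + t.area - ix * iy)
    cw = max(p.x2, t.x2) - min(p.x1, t.x1)
    ch = max(p.y2, t.y2) - min(p.y1, t.y1)
    r_wiou = math.exp(((p.cx - t.cx) ** 2 + (p.cy - t.cy) ** 2)
                      / (cw ** 2 + ch ** 2 + 1e-12))
    beta = liou / max(state.mean_iou_loss, state.floor)
    expo = beta - (state.delta_focus if state.exponent == "reference" else state.alpha)
    r = beta / (state.delta_focus * state.alpha ** expo)
    return r * r_wiou * liou


class TestIou:
    def test_identity_disjoint_and_overlap(self):
        a = BoundingBox(3, -2, 5, 4)
        assert iou(a, a) == 1.0
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(10, 10, 2, 2)) == 0.0
        got = iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 2, 2))
        assert got == pytest.approx(1 / 7, abs=1e-12)
        assert rasterized_iou(BoundingBox(0, 0, 2, 2),
                              BoundingBox(1, 1, 2, 2)) == pytest.approx(1 / 7, abs=2e-3)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(a=box_strategy, b=box_strategy)
    def test_symmetry_and_bounds(self, a, b):
        assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)
        assert 0.0 <= iou(a, b) <= 1.0
        assert ciou_loss(a, b) >= 0.0
        assert wiou_loss(a, b, WiouState()) >= 0.0

    def test_degenerate_boxes_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 0, 0.0, 2)
        with pytest.raises(ValueError):
            BoundingBox(0, 0, 2, -1)


class TestCiou:
    def test_zero_for_identical(self):
        b = BoundingBox(5, 7, 3, 9)
        assert ciou_loss(b, b) == pytest.approx(0.0, abs=1e-9)

    def test_concentric_squares(self):
        # IOU 4/16, no center offset, equal aspect ratios
        got = ciou_loss(BoundingBox(0, 0, 2, 2), BoundingBox(0, 0, 4, 4))
        assert got == pytest.approx(0.75, abs=1e-9)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(1000):
            p, t = random_box(rng), random_box(rng)
            assert ciou_loss(p, t) == pytest.approx(ciou_oracle(p, t), abs=1e-9)

    def test_monotone_in_center_distance(self):
        target = BoundingBox(0, 0, 6, 6)
        losses = [ciou_loss(BoundingBox(d, 0.5 * d, 6, 6), target)
                  for d in np.linspace(0, 30, 40)]
        assert np.all(np.diff(losses) >= -1e-12)


class TestWiou:
    def test_zero_for_identical(self):
        b = BoundingBox(1, 2, 3, 4)
        assert wiou_loss(b, b, WiouState()) == 0.0

    def test_reduces_to_iou_loss_when_attention_and_focus_are_unit(self):
        # concentric boxes make R = exp(0) = 1; mean = L/delta makes beta = delta
        # hence r = 1 under the reference exponent, leaving exactly 1 - IOU.
        p, t = BoundingBox(0, 0, 2, 2), BoundingBox(0, 0, 4, 4)
        liou = 1 - iou(p, t)
        state = WiouState(mean_iou_loss=liou / 3.0, delta_focus=3.0)
        assert wiou_loss(p, t, state) == pytest.approx(liou, abs=1e-12)

    def test_focusing_coefficient_is_one_at_beta_equals_delta(self):
        state = WiouState(mean_iou_loss=0.2, delta_focus=3.0, alpha=1.9)
        p = BoundingBox(0, 0, 2, 2)
        # concentric same-height boxes: IOU equals the width ratio, so this
        # pair has IOU loss 0.6 = delta * mean, i.e. beta = delta exactly
        t = BoundingBox(0, 0, 2 * 0.4, 2)
        liou = 1 - iou(p, t)
        assert liou == pytest.approx(0.6, abs=1e-12)
        assert wiou_loss(p, t, state) == pytest.approx(liou, abs=1e-12)

    def test_printed_exponent_switch(self):
        p, t = BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 2, 2)
        ref = wiou_loss(p, t, WiouState(mean_iou_loss=0.3, exponent="reference"))
        pap = wiou_loss(p, t, WiouState(mean_iou_loss=0.3, exponent="printed"))
        st = WiouState(mean_iou_loss=0.3, exponent="printed")
        assert pap == pytest.approx(wiou_oracle(p, t, st), abs=1e-12)
        assert ref != pytest.approx(pap)  # alpha != delta so the forms differ

    def test_matches_symbol_by_symbol_oracle(self, rng):
        state = WiouState(mean_iou_loss=0.37)
        for _ in range(1000):
            p, t = random_box(rng), random_box(rng)
            assert wiou_loss(p, t, state) == pytest.approx(
                wiou_oracle(p, t, state), abs=1e-9)

    def test_requires_positive_running_mean(self):
        with pytest.raises(ValueError):
            WiouState(mean_iou_loss=0.0)


class TestWiouState:
    def test_full_replacement_fixed_point_and_sliding(self):
        st = WiouState(mean_iou_loss=0.9, momentum=1e-9)
        assert update_wiou_state(st, [0.4, 0.6]).mean_iou_loss == pytest.approx(0.5)
        st = WiouState(mean_iou_loss=0.5, momentum=0.9)
        assert update_wiou_state(st, [0.5, 0.5]).mean_iou_loss == pytest.approx(0.5)
        st = WiouState(mean_iou_loss=0.2, momentum=0.9)
        assert update_wiou_state(st, [0.7]).mean_iou_loss == pytest.approx(0.25)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            update_wiou_state(WiouState(), [])

    def test_stays_in_unit_interval(self, rng):
        st = WiouState(mean_iou_loss=0.5)
        for _ in range(50):
            st = update_wiou_state(st, rng.uniform(0, 1, size=5))
            assert 0.0 <= st.mean_iou_loss <= 1.0


class TestBatchedLosses:
    """The autodiff (training-path) losses against the scalar reference."""

    def _pairs(self, rng, n=200):
        p = np.array([[b.cx, b.cy, b.w, b.h] for b in (random_box(rng) for _ in range(n))])
        t = np.array([[b.cx, b.cy, b.w, b.h] for b in (random_box(rng) for _ in range(n))])
        return p, t

    def test_batched_matches_scalar(self, rng):
        p, t = self._pairs(rng)
        state = WiouState(mean_iou_loss=0.4)
        got_iou = batched_iou(Tensor(p), Tensor(t)).data
        got_ciou = batched_ciou_loss(Tensor(p), Tensor(t)).data
        got_wiou = batched_wiou_loss(Tensor(p), Tensor(t), state).data
        for k in range(len(p)):
            a, b = BoundingBox(*p[k]), BoundingBox(*t[k])
            assert got_iou[k] == pytest.approx(iou(a, b), abs=1e-9)
            assert got_ciou[k] == pytest.approx(ciou_loss(a, b), abs=1e-9)
            assert got_wiou[k] == pytest.approx(wiou_loss(a, b, state), abs=1e-9)

    def test_starred_terms_carry_no_gradient(self, rng):
        """Autodiff gradient equals finite differences of the loss with the
        enclosure denominator and the outlier degree frozen at their values."""
        p, t = self._pairs(rng, n=4)
        state = WiouState(mean_iou_loss=0.4)
        pred = Tensor(p, requires_grad=True)
        batched_wiou_loss(pred, Tensor(t), state).sum().backward()

        liou0 = 1.0 - batched_iou(Tensor(p), Tensor(t)).data
        cw0 =(np.maximum(p[:, 0] + p[:, 2] / 2, t[:, 0] + t[:, 2] / 2)
               - np.minimum(p[:, 0] - p[:, 2] / 2, t[:, 0] - t[:, 2] / 2))
        ch0 = (np.maximum(p[:, 1] + p[:, 3] / 2, t[:, 1] + t[:, 3] / 2)
               - np.minimum(p[:, 1] - p[:, 3] / 2, t[:, 1] - t[:, 3] / 2))
        denom0 = cw0 ** 2 + ch0 ** 2
        beta0 = liou0 / state.mean_iou_loss
        r0 = beta0 / (state.delta_focus
                      * state.alpha ** (beta0 - state.delta_focus))

        def frozen_loss():
            total = 0.0
            for k in range(len(p)):
                a, b = BoundingBox(*pred.data[k]), BoundingBox(*t[k])
                liou = 1 - iou(a, b)
                r_w = math.exp(((a.cx - b.cx) ** 2 + (a.cy - b.cy) ** 2)
                               / (denom0[k] + 1e-12))
                total += r0[k] * r_w * liou
            return total

        fd = finite_difference(pred, frozen_loss, eps=1e-6)
        assert np.abs(fd - pred.grad).max() < 1e-5


class TestLabelIO:
    def test_roundtrip_and_range(self, tmp_path, rng):
        boxes = [BoundingBox(100.3, 57.2, 30.5, 12.8), BoundingBox(5, 5, 9, 9)]
        path = tmp_path / "labels.txt"
        write_yolo_labels(path, boxes, [0, 0], 320, 240)
        for line in path.read_text().splitlines():
            vals = [float(v) for v in line.split()[1:]]
            assert all(0.0 <= v <= 1.0 for v in vals)
        back, cids = read_yolo_labels(path, 320, 240)
        for orig, rec in zip(boxes, back):
            assert abs(orig.cx - rec.cx) < 0.5 and abs(orig.w - rec.w) < 0.5

    def test_out_of_frame_box_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_yolo_labels(tmp_path / "l.txt", [BoundingBox(300, 10, 100, 5)],
                              [0], 320, 240)
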