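"""Bounding boxes and IOU-family regression losses.

Boxes live in pixel-space center format ``(cx, cy, w, h)``; labels on disk use
the normalized YOLO text format and are converted explicitly.  Three losses
are provided:

* plain IOU loss ``1 - IOU``;
* complete IOU (CIOU): IOU loss plus a normalized center-distance penalty
  ``rho^2 / c^2`` and an aspect-ratio consistency term ``alpha * v``;
* Wise-IOU: IOU loss scaled by a distance-attention factor ``R = exp(rho^2 /
  (cw^2 + ch^2))`` and a non-monotonic focusing coefficient ``r`` driven by
  the outlier degree ``beta`` (the ratio of the current IOU loss to a running
  mean of IOU losses).  Quantities marked as non-backpropagated contribute
  their value only; the batched tensor variants below detach them.

The scalar functions operate on :class:`BoundingBox` and plain floats; the
``batched_*`` functions operate on ``(n, 4)`` autodiff tensors and are what
the detector's training step uses.  Both implement the same formulas and are
cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, maximum

__all__ = [
    "BoundingBox",
    "EnclosureGeometry",
    "WiouState",
    "LossComponents",
    "iou",
    "iou_loss",
    "ciou_loss",
    "wiou_loss",
    "update_wiou_state",
    "enclosure",
    "read_yolo_labels",
    "write_yolo_labels",
    "batched_iou",
    "batched_ciou_loss",
    "batched_wiou_loss",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, center format."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_corners(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    @staticmethod
    def from_corners(x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return BoundingBox((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def to_normalized(self, image_w: int, image_h: int) -> tuple[float, float, float, float]:
        return (self.cx / image_w, self.cy / image_h, self.w / image_w, self.h / image_h)

    @staticmethod
    def from_normalized(cx: float, cy: float, w: float, h: float,
                        image_w: int, image_h: int) -> "BoundingBox":
        return BoundingBox(cx * image_w, cy * image_h, w * image_w, h * image_h)


@dataclass(frozen=True)
class EnclosureGeometry:
    """Geometry of the smallest box enclosing a prediction/target pair."""

    rho2: float   # squared center distance, px^2
    c2: float     # squared diagonal of the enclosing box, px^2
    cw: float     # enclosing-box width, px
    ch: float     # enclosing-box height, px


@dataclass
class WiouState:
    """Running normalizer and focusing hyperparameters for Wise-IOU.

    ``mean_iou_loss`` is the sliding average of batch IOU losses used to
    compute the outlier degree beta; ``alpha`` and ``delta`` shape the
    non-monotonic focusing coefficient r (r = 1 when beta = delta under the
    reference exponent).
    """

    mean_iou_loss: float = 1.0
    momentum: float = 0.99
    alpha: float = 1.9
    delta_focus: float = 3.0
    floor: float = 1e-4
    exponent: str = "reference"  # "reference" (beta-delta) or "printed" (beta-alpha)

    def __post_init__(self):
        if not (0.0 < self.momentum < 1.0):
            raise ValueError("momentum must lie in (0,1)")
        if self.alpha <= 0 or self.delta_focus <= 0:
            raise ValueError("focusing hyperparameters must be positive")
        if self.exponent not in ("reference", "printed"):
            raise ValueError("exponent must be 'reference' or 'printed'")
        if self.mean_iou_loss <= 0:
            raise ValueError("mean_iou_loss must be positive")


@dataclass(frozen=True)
class LossComponents:
    """Weighted loss terms of one training step."""

    box_loss: float
    cls_loss: float
    box_weight: float
    cls_weight: float

    @property
    def total(self) -> float:
        return self.box_weight * self.box_loss + self.cls_weight * self.cls_loss


# ------------------------------------------------------------ scalar losses

def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area of two valid boxes."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return min(max(inter / union, 0.0), 1.0)


def iou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    return 1.0 - iou(pred, target)


def enclosure(a: BoundingBox, b: BoundingBox) -> EnclosureGeometry:
    cw = max(a.x2, b.x2) - min(a.x1, b.x1)
    ch = max(a.y2, b.y2) - min(a.y1, b.y1)
    rho2 = (a.cx - b.cx) ** 2 + (a.cy - b.cy) ** 2
    return EnclosureGeometry(rho2=rho2, c2=cw * cw + ch * ch, cw=cw, ch=ch)


def ciou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    """Complete-IOU loss: 1 - IOU + rho^2/c^2 + alpha*v."""
    i = iou(pred, target)
    geo = enclosure(pred, target)
    v = (4.0 / math.pi ** 2) * (
        math.atan(target.w / target.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - i) + v + _EPS)
    return (1.0 - i) + geo.rho2 / (geo.c2 + _EPS) + alpha * v


def _focusing_coefficient(beta: float, state: WiouState) -> float:
    a, d = state.alpha, state.delta_focus
    expo = beta - (d if state.exponent == "reference" else a)
    return beta / (d * a ** expo)


def wiou_loss(pred: BoundingBox, target: BoundingBox, state: WiouState) -> float:
    """Wise-IOU loss: r * R * (1 - IOU) with distance attention and focusing."""
    if state.mean_iou_loss <= 0:
        raise ValueError("state.mean_iou_loss must be positive")
    liou = 1.0 - iou(pred, target)
    geo = enclosure(pred, target)
    r_wiou = math.exp(geo.rho2 / (geo.c2 + _EPS))
    beta = liou / max(state.mean_iou_loss, state.floor)
    return _focusing_coefficient(beta, state) * r_wiou * liou


def update_wiou_state(state: WiouState, batch_iou_losses: Sequence[float]) -> WiouState:
    """Sliding-average update of the running mean IOU loss (returns a new state)."""
    values = np.asarray(list(batch_iou_losses), dtype=np.float64)
    if values.size == 0:
        raise ValueError("batch of IOU losses must be non-empty")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("IOU losses must lie in [0,1]")
    m = state.momentum
    new_mean = m * state.mean_iou_loss + (1.0 - m) * float(values.mean())
    return replace(state, mean_iou_loss=max(new_mean, state.floor))


# ---------------------------------------------------------------- label I/O

def write_yolo_labels(path: str | Path, boxes: Iterable[BoundingBox],
                      class_ids: Iterable[int], image_w: int, image_h: int) -> None:
    """Write one 'class cx cy w h' line per box, coordinates normalized to [0,1]."""
    lines = []
    for box, cid in zip(boxes, class_ids):
        if box.x1 < 0 or box.y1 < 0 or box.x2 > image_w or box.y2 > image_h:
            raise ValueError(f"box {box} extends outside the {image_w}x{image_h} frame")
        cx, cy, w, h = box.to_normalized(image_w, image_h)
        lines.append(f"{int(cid)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path: str | Path, image_w: int, image_h: int
                     ) -> tuple[list[BoundingBox], list[int]]:
    boxes, class_ids = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cid, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
        boxes.append(BoundingBox.from_normalized(cx, cy, w, h, image_w, image_h))
        class_ids.append(cid)
    return boxes, class_ids


# ------------------------------------------------------- batched (autodiff)

def _corners(t: Tensor):
    cx, cy, w, h = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    return cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5


def batched_iou(pred: Tensor, target: Tensor) -> Tensor:
    """IOU of paired (n,4) center-format boxes, differentiable."""
    pred, target = as_tensor(pred), as_tensor(target)
    px1, py1, px2, py2 = _corners(pred)
    tx1, ty1, tx2, ty2 = _corners(target)
    ix = maximum(_minimum(px2, tx2) - maximum(px1, tx1), 0.0)
    iy = maximum(_minimum(py2, ty2) - maximum(py1, ty1), 0.0)
    inter = ix * iy
    union = pred[:, 2] * pred[:, 3] + target[:, 2] * target[:, 3] - inter
    return inter / (union + _EPS)


def _minimum(a, b):
    return -maximum(-as_tensor(a), -as_tensor(b))


def batched_ciou_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Per-pair CIOU loss of (n,4) tensors; alpha is held constant in the graph."""
    pred, target = as_tensor(pred), as_tensor(target)
    i = batched_iou(pred, target)
    px1, py1, px2, py2 = _corners(pred)
    tx1, ty1, tx2, ty2 = _corners(target)
    cw = maximum(px2, tx2) - _minimum(px1, tx1)
    ch = maximum(py2, ty2) - _minimum(py1, ty1)
    c2 = cw * cw + ch * ch
    rho2 = (pred[:, 0] - target[:, 0]) ** 2 + (pred[:, 1] - target[:, 1]) ** 2
    v = (4.0 / math.pi ** 2) * \
        ((target[:, 2] / target[:, 3]).arctan() - (pred[:, 2] / pred[:, 3]).arctan()) ** 2
    alpha = (v / ((1.0 - i) + v + _EPS)).detach()
    return (1.0 - i) + rho2 / (c2 + _EPS) + alpha * v


def batched_wiou_loss(pred: Tensor, target: Tensor, state: WiouState) -> Tensor:
    """Per-pair Wise-IOU loss; starred quantities are detached from the graph."""
    pred, target = as_tensor(pred), as_tensor(target)
    liou = 1.0 - batched_iou(pred, target)
    px1, py1, px2, py2 = _corners(pred)
    tx1, ty1, tx2, ty2 = _corners(target)
    cw = maximum(px2, tx2) - _minimum(px1, tx1)
    ch = maximum(py2, ty2) - _minimum(py1, ty1)
    denom = (cw * cw + ch * ch).detach()   # not participating in backpropagation
    rho2 = (pred[:, 0] - target[:, 0]) ** 2 + (pred[:, 1] - target[:, 1]) ** 2
    r_wiou = (rho2 / (denom + _EPS)).exp()
    beta = liou.data / max(state.mean_iou_loss, state.floor)   # detached
    a, d = state.alpha, state.delta_focus
    expo = beta - (d if state.exponent == "reference" else a)
    r = Tensor(beta / (d * a ** expo))     # focusing coefficient, constant in the graph
    return r * r_wiou * liou
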