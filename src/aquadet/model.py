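"""The miniature multi-scale fish detector.

Architecture
------------
A cross-stage backbone downsamples the input by 2 at the stem and at each of
four stages, yielding pyramid features at strides 4/8/16/32.  A top-down neck
upsamples and concatenates adjacent levels, with an optional channel-attention
block after every neck stage.  Anchor-free heads predict, per grid cell, a
center offset, a log-scale box size, an objectness logit and per-class logits.

With ``small_head`` enabled the finest (stride-4) level carries its own head,
so a 640-px input produces 160/80/40/20 grids; without it the standard
80/40/20 triple is produced.  ``use_dcn`` makes the deepest backbone stage's
cross-stage block deformable (both bottleneck convolutions plus a
resolution-preserving deformable pooling stage).

Box decoding (per cell ``(i, j)`` at stride ``s``)::

    cx = (j + 0.5 + (4*sigmoid(tx) - 2)) * s      # +-2 cells of freedom
    w  = (2*sigmoid(tw))**2 * 2 * s               # (0, 8 s]

so every positive neighbour cell can regress the same object and sizes stay
bounded.

Target assignment follows the heads' design sizes — a stride-``s`` grid
detects targets of max side ``s`` and above (up to the decoder's 8s cap), so
a box is supervised at every scale in that window — and marks the center cell
plus its two nearest neighbour cells positive on each.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import SGD, Tensor, bce_with_logits, concat, upsample2x
from .boxes import (BoundingBox, LossComponents, WiouState, batched_ciou_loss,
                    batched_wiou_loss, iou, update_wiou_state)
from .nn import C2f, ChannelAttention, Conv2d, ConvBlock, Module

__all__ = [
    "ArchitectureConfig",
    "Detection",
    "Detector",
    "build_model",
    "assign_targets",
    "encode_box",
    "detection_loss",
    "training_step",
    "predict",
    "nms",
    "save_checkpoint",
    "load_checkpoint",
]

BOX_WEIGHT = 5.0
CLS_WEIGHT = 1.0
POS_OBJ_WEIGHT = 16.0   # relative BCE weight of positive cells (objectness)

_BASE_CHANNELS = (32, 64, 128, 256, 256)   # stem + four stages, before width_mult


@dataclass
class ArchitectureConfig:
    """Build-time switches of the detector."""

    input_size: int = 640
    width_mult: float = 0.25
    depth_mult: float = 1.0
    num_classes: int = 1
    use_dcn: bool = True
    attention: str = "dpse"          # none | se | dpse
    small_head: bool = True
    box_loss: str = "wiou"           # ciou | wiou
    wiou_exponent: str = "reference"  # reference (beta-delta) | printed (beta-alpha)

    def __post_init__(self):
        if self.attention not in ("none", "se", "dpse"):
            raise ValueError("attention must be none|se|dpse")
        if self.box_loss not in ("ciou", "wiou"):
            raise ValueError("box_loss must be ciou|wiou")
        if self.input_size % max(self.strides) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by {max(self.strides)}")

    @property
    def strides(self) -> list[int]:
        return [4, 8, 16, 32] if self.small_head else [8, 16, 32]

    @property
    def channels(self) -> list[int]:
        return [max(4, int(round(c * self.width_mult))) for c in _BASE_CHANNELS]

    @property
    def depth(self) -> int:
        return max(1, int(round(self.depth_mult)))


@dataclass(frozen=True)
class Detection:
    """One predicted object: pixel box, confidence and class."""

    box: BoundingBox
    score: float
    class_id: int = 0


class Detector(Module):
    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator):
        self.cfg = cfg
        c1, c2, c3, c4, c5 = cfg.channels
        n = cfg.depth
        self.stem = ConvBlock(3, c1, 3, 2, rng=rng)
        self.down2 = ConvBlock(c1, c2, 3, 2, rng=rng)
        self.c2f2 = C2f(c2, c2, n, rng=rng)
        self.down3 = ConvBlock(c2, c3, 3, 2, rng=rng)
        self.c2f3 = C2f(c3, c3, n, rng=rng)
        self.down4 = ConvBlock(c3, c4, 3, 2, rng=rng)
        self.c2f4 = C2f(c4, c4, n, rng=rng)
        self.down5 = ConvBlock(c4, c5, 3, 2, rng=rng)
        self.c2f5 = C2f(c5, c5, n, deformable=cfg.use_dcn, rng=rng)

        self.neck4 = C2f(c5 + c4, c4, n, rng=rng)
        self.neck3 = C2f(c4 + c3, c3, n, rng=rng)
        self.neck2 = C2f(c3 + c2, c2, n, rng=rng) if cfg.small_head else None

        if cfg.attention != "none":
            kinds = [c5, c4, c3] + ([c2] if cfg.small_head else [])
            self.attn = [ChannelAttention(c, cfg.attention, rng=rng) for c in kinds]
        else:
            self.attn = []

        out_ch = 5 + cfg.num_classes
        head_channels = ([c2] if cfg.small_head else []) + [c3, c4, c5]
        self.heads = []
        for c in head_channels:
            self.heads.append(ConvBlock(c, c, 3, rng=rng))
            final = Conv2d(c, out_ch, 1, bias=True, rng=rng)
            # low-prior objectness init: cells start near-silent, so early
            # steps train the boxes instead of suppressing a flood of random
            # false positives
            final.bias.data[4] = -4.0
            self.heads.append(final)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Run the network; returns one (B, 5+nc, H/s, W/s) grid per stride."""
        p1 = self.stem(x)
        p2 = self.c2f2(self.down2(p1))
        p3 = self.c2f3(self.down3(p2))
        p4 = self.c2f4(self.down4(p3))
        p5 = self.c2f5(self.down5(p4))

        att = iter(self.attn) if self.attn else None

        def a(t):
            return next(att)(t) if att is not None else t

        n5 = a(p5)
        n4 = a(self.neck4(concat([upsample2x(n5), p4], axis=1)))
        n3 = a(self.neck3(concat([upsample2x(n4), p3], axis=1)))
        levels = [n3, n4, n5]
        if self.cfg.small_head:
            n2 = a(self.neck2(concat([upsample2x(n3), p2], axis=1)))
            levels = [n2] + levels
        outs = []
        for i, lvl in enumerate(levels):
            outs.append(self.heads[2 * i + 1](self.heads[2 * i](lvl)))
        return outs

    __call__ = forward


def build_model(cfg: ArchitectureConfig, seed: int = 0) -> Detector:
    """Construct a detector with reproducible initialization."""
    return Detector(cfg, np.random.default_rng(seed))


# ----------------------------------------------------------- target encoding

_SIZE_CAP = 8.0  # the decoder can represent sizes up to 8 * stride


def _assign_levels(size: float, strides: Sequence[int]) -> list[int]:
    """Levels whose stride can detect a box of max side ``size``.

    A stride-s grid handles targets of size s and above, up to the decoder's
    representable cap of 8s, so a box is supervised at every scale in that
    window (a large fish appears on the fine grids too, which is where
    localization is most precise).  Boxes below the finest stride fall back
    to the finest grid; boxes above every cap fall back to the coarsest.
    """
    levels = [i for i, s in enumerate(strides)
              if s <= size <= _SIZE_CAP * s]
    if not levels:
        return [0] if size < strides[0] else [len(strides) - 1]
    return levels


def assign_targets(gt_boxes: Sequence[BoundingBox], strides: Sequence[int],
                   grid_shapes: Sequence[tuple[int, int]],
                   class_ids: Sequence[int] | None = None):
    """Assign ground-truth boxes to grid cells.

    Returns, per level, a dict with integer arrays ``rows``/``cols``, a
    ``(n, 4)`` array of target boxes (pixels, center format) and ``classes``.
    Each box is supervised at every scale whose stride window covers its max
    side (see :func:`_assign_levels`); on each such grid it marks its center
    cell plus the two nearest neighbour cells (the ones its center is offset
    toward) positive.  A cell claimed by several boxes regresses the one
    whose center is nearest, so crowded scenes give every cell its locally
    dominant target while coarse grids keep genuine negatives.
    """
    if class_ids is None:
        class_ids = [0] * len(gt_boxes)
    per_level = [{"rows": [], "cols": [], "boxes": [], "classes": []}
                 for _ in strides]
    claims: list[dict[tuple[int, int], tuple[float, list, int]]] = \
        [{} for _ in strides]
    for box, cid in zip(gt_boxes, class_ids):
        for lvl in _assign_levels(max(box.w, box.h), strides):
            s = strides[lvl]
            H, W = grid_shapes[lvl]
            gx, gy = box.cx / s, box.cy / s
            cj = min(max(int(gx), 0), W - 1)
            ci = min(max(int(gy), 0), H - 1)
            nj = cj + (1 if gx - cj > 0.5 else -1)
            ni = ci + (1 if gy - ci > 0.5 else -1)
            cells = [(ci, cj)]
            if 0 <= nj < W:
                cells.append((ci, nj))
            if 0 <= ni < H:
                cells.append((ni, cj))
            for (i, j) in cells:
                dist = (gy - (i + 0.5)) ** 2 + (gx - (j + 0.5)) ** 2
                prev = claims[lvl].get((i, j))
                if prev is None or dist < prev[0]:
                    claims[lvl][(i, j)] = (dist, [box.cx, box.cy, box.w, box.h], cid)
    for lvl, lvl_claims in enumerate(claims):
        d = per_level[lvl]
        for (i, j), (_, tbox, cid) in sorted(lvl_claims.items()):
            d["rows"].append(i)
            d["cols"].append(j)
            d["boxes"].append(tbox)
            d["classes"].append(cid)
    for d in per_level:
        d["rows"] = np.asarray(d["rows"], dtype=np.int64)
        d["cols"] = np.asarray(d["cols"], dtype=np.int64)
        d["boxes"] = np.asarray(d["boxes"], dtype=np.float64).reshape(-1, 4)
        d["classes"] = np.asarray(d["classes"], dtype=np.int64)
    return per_level


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def encode_box(box: BoundingBox, row: int, col: int, stride: int
               ) -> tuple[float, float, float, float]:
    """Invert the decoding: logits that decode exactly to ``box`` at a cell."""
    tx = _logit(((box.cx / stride - col - 0.5) + 2.0) / 4.0)
    ty = _logit(((box.cy / stride - row - 0.5) + 2.0) / 4.0)
    tw = _logit(np.sqrt(box.w / (2.0 * stride)) / 2.0)
    th = _logit(np.sqrt(box.h / (2.0 * stride)) / 2.0)
    return tx, ty, tw, th


def _decode_positives(raw: Tensor, rows: np.ndarray, cols: np.ndarray,
                      stride: int) -> Tensor:
    """Decode gathered (n, >=4) head outputs into (n, 4) pixel boxes."""
    txy = raw[:, 0:2].sigmoid() * 4.0 - 2.0
    grid = np.stack([cols + 0.5, rows + 0.5], axis=1)
    centers = (txy + grid) * float(stride)
    wh = ((raw[:, 2:4].sigmoid() * 2.0) ** 2.0) * (2.0 * stride)
    return concat([centers, wh], axis=1)


def decode_grid(out: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode a full (5+nc, H, W) output grid (numpy, inference path).

    Returns ``(boxes (H*W, 4), scores (H*W, nc))`` where the score is
    sigmoid(objectness) * sigmoid(class logit).
    """
    _, H, W = out.shape
    sig = 1.0 / (1.0 + np.exp(-out))
    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    cx = (jj + 0.5 + (4 * sig[0] - 2)) * stride
    cy = (ii + 0.5 + (4 * sig[1] - 2)) * stride
    w = (2 * sig[2]) ** 2 * 2 * stride
    h = (2 * sig[3]) ** 2 * 2 * stride
    boxes = np.stack([cx, cy, w, h], axis=-1).reshape(-1, 4)
    scores = (sig[4] * sig[5:]).reshape(out.shape[0] - 5, -1).T
    return boxes, scores


# ------------------------------------------------------------------- losses

def detection_loss(outputs: list[Tensor], scenes: Sequence, cfg: ArchitectureConfig,
                   state: WiouState | None = None):
    """Box + classification loss over a batch of ground-truth scenes.

    Returns ``(total: Tensor, components: LossComponents, new_state)``.  The
    classification component is the objectness BCE over every cell (positives
    up-weighted) plus the per-class BCE on positive cells.
    """
    strides = cfg.strides
    grid_shapes = [tuple(o.shape[2:]) for o in outputs]
    assignments = [assign_targets(sc.boxes, strides, grid_shapes,
                                  getattr(sc, "class_ids", None)) for sc in scenes]

    box_terms, liou_values = [], []
    n_pos_total = 0
    obj_losses, cls_losses = [], []
    for lvl, out in enumerate(outputs):
        B, _, H, W = out.shape
        perm = out.transpose(0, 2, 3, 1)          # (B,H,W,5+nc)
        b_idx, rows, cols, tboxes, tcls = [], [], [], [], []
        for b, asg in enumerate(assignments):
            d = asg[lvl]
            b_idx += [b] * len(d["rows"])
            rows.append(d["rows"])
            cols.append(d["cols"])
            tboxes.append(d["boxes"])
            tcls.append(d["classes"])
        b_idx = np.asarray(b_idx, dtype=np.int64)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        tboxes = np.concatenate(tboxes)
        tcls = np.concatenate(tcls)

        iou_q = None
        if len(b_idx):
            gathered = perm[b_idx, rows, cols]    # (n, 5+nc)
            pred_boxes = _decode_positives(gathered, rows, cols, strides[lvl])
            iou_q = _pair_iou_np(pred_boxes.data, tboxes)
            target = Tensor(tboxes)
            if cfg.box_loss == "wiou":
                st = state if state is not None \
                    else WiouState(exponent=cfg.wiou_exponent)
                pair = batched_wiou_loss(pred_boxes, target, st)
                liou_values.append(1.0 - iou_q)
            else:
                pair = batched_ciou_loss(pred_boxes, target)
            box_terms.append(pair.sum())
            n_pos_total += len(b_idx)

            onehot = np.zeros((len(b_idx), cfg.num_classes))
            onehot[np.arange(len(b_idx)), tcls] = 1.0
            cls_losses.append(bce_with_logits(gathered[:, 5:], onehot))

        # Objectness: positives are up-weighted and supervised toward the IOU
        # of their currently decoded box (detached), so the confidence learns
        # to rank well-localized predictions first.
        obj_target = np.zeros((B, H, W))
        obj_weight = np.ones((B, H, W))
        if len(b_idx):
            obj_target[b_idx, rows, cols] = np.clip(iou_q, 0.0, 1.0)
            obj_weight[b_idx, rows, cols] = POS_OBJ_WEIGHT
        obj_losses.append(bce_with_logits(perm[:, :, :, 4], obj_target, obj_weight))

    obj_loss = _mean_terms(obj_losses)
    cls_loss = _mean_terms(cls_losses) if cls_losses else Tensor(0.0)
    box_loss = (_sum_terms(box_terms) * (1.0 / n_pos_total)) if n_pos_total \
        else Tensor(0.0)
    total = BOX_WEIGHT * box_loss + CLS_WEIGHT * (obj_loss + cls_loss)

    new_state = state
    if state is not None and cfg.box_loss == "wiou" and liou_values:
        new_state = update_wiou_state(
            state, np.clip(np.concatenate(liou_values), 0.0, 1.0))

    comps = LossComponents(box_loss=float(box_loss.data),
                           cls_loss=float(obj_loss.data) + float(cls_loss.data),
                           box_weight=BOX_WEIGHT, cls_weight=CLS_WEIGHT)
    return total, comps, new_state


def _sum_terms(terms):
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def _mean_terms(terms):
    return _sum_terms(terms) * (1.0 / len(terms))


def _pair_iou_np(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ax1, ay1 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax2, ay2 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx1, by1 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx2, by2 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax2, bx2) - np.maximum(ax1, bx1), 0, None)
    ih = np.clip(np.minimum(ay2, by2) - np.maximum(ay1, by1), 0, None)
    inter = iw * ih
    union = a[:, 2] * a[:, 3] + b[:, 2] * b[:, 3] - inter
    return inter / (union + 1e-12)


def scenes_to_batch(scenes: Sequence) -> Tensor:
    """Stack scene images into a (B,3,H,W) tensor scaled to [0,1]."""
    imgs = [np.asarray(sc.image, dtype=np.float64).transpose(2, 0, 1) / 255.0
            for sc in scenes]
    return Tensor(np.stack(imgs))


def training_step(model: Detector, scenes: Sequence, state: WiouState | None = None,
                  optimizer: SGD | None = None) -> tuple[LossComponents, WiouState | None]:
    """One forward/backward pass over a batch of scenes.

    Applies an optimizer step when ``optimizer`` is given, updates the
    Wise-IOU running mean when that loss is selected, and raises on
    non-finite losses.
    """
    if not len(scenes):
        raise ValueError("batch must be non-empty")
    outputs = model(scenes_to_batch(scenes))
    total, comps, state = detection_loss(outputs, scenes, model.cfg, state)
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite loss: box={comps.box_loss}, cls={comps.cls_loss}")
    if optimizer is not None:
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
    return comps, state


# ---------------------------------------------------------------- inference

def nms(detections: list[Detection], iou_threshold: float = 0.5,
        merge: bool = False) -> list[Detection]:
    """Greedy non-maximum suppression, per class, by descending score.

    With ``merge=True`` each kept detection's box is replaced by the
    score-weighted average of its suppressed cluster (box voting).  The
    prediction grids produce several near-duplicate boxes per object — often
    from different pyramid levels — and averaging these independent estimates
    tightens localization; scores are left untouched.
    """
    kept: list[Detection] = []
    for cid in sorted({d.class_id for d in detections}):
        cand = sorted([d for d in detections if d.class_id == cid],
                      key=lambda d: -d.score)
        chosen: list[Detection] = []
        clusters: list[list[Detection]] = []
        for det in cand:
            suppressed = False
            for k, keeper in enumerate(chosen):
                if iou(det.box, keeper.box) > iou_threshold:
                    clusters[k].append(det)
                    suppressed = True
                    break
            if not suppressed:
                chosen.append(det)
                clusters.append([det])
        if merge:
            merged = []
            for keeper, cluster in zip(chosen, clusters):
                wts = np.array([d.score for d in cluster])
                arr = np.array([[d.box.cx, d.box.cy, d.box.w, d.box.h]
                                for d in cluster])
                cx, cy, w, h = (arr * wts[:, None]).sum(axis=0) / wts.sum()
                merged.append(Detection(BoundingBox(cx, cy, w, h),
                                        keeper.score, cid))
            chosen = merged
        kept.extend(chosen)
    return sorted(kept, key=lambda d: -d.score)


def predict(model: Detector, image: np.ndarray, conf_threshold: float = 0.25,
            nms_iou: float = 0.5, max_det: int = 300,
            merge: bool = True) -> list[Detection]:
    """Detect objects in one HxWx3 uint8 image.

    Decodes every grid cell, keeps cells whose best class score clears the
    confidence threshold, clips boxes to the image and applies greedy NMS
    with box voting (see :func:`nms`).  Deterministic for a fixed input and
    model.
    """
    was_training = model.training
    model.eval()
    try:
        img_h, img_w = image.shape[:2]

        class _Scene:
            pass

        sc = _Scene()
        sc.image = image
        outputs = model(scenes_to_batch([sc]))
    finally:
        model.train(was_training)
    dets: list[Detection] = []
    for out, stride in zip(outputs, model.cfg.strides):
        boxes, scores = decode_grid(out.data[0], stride)
        best_c = scores.argmax(axis=1)
        best_s = scores[np.arange(len(scores)), best_c]
        for k in np.nonzero(best_s >= conf_threshold)[0]:
            cx, cy, w, h = boxes[k]
            x1 = np.clip(cx - w / 2, 0, img_w - 1)
            y1 = np.clip(cy - h / 2, 0, img_h - 1)
            x2 = np.clip(cx + w / 2, x1 + 1e-3, img_w)
            y2 = np.clip(cy + h / 2, y1 + 1e-3, img_h)
            dets.append(Detection(BoundingBox.from_corners(x1, y1, x2, y2),
                                  float(best_s[k]), int(best_c[k])))
    return nms(dets, nms_iou, merge=merge)[:max_det]


# -------------------------------------------------------------- checkpoints

def save_checkpoint(model: Detector, path: str | Path) -> None:
    """Write the model as a flat name -> array archive (.npz)."""
    np.savez(path, **model.state_dict())


def load_checkpoint(model: Detector, path: str | Path) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
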