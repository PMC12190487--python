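"""Training loop, model evaluation and the ablation harness."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .autodiff import SGD
from .boxes import BoundingBox, LossComponents, WiouState
from .config import RunConfig
from .metrics import MetricsReport, evaluate_detections
from .model import Detector, build_model, predict, training_step
from .scenes import GroundTruthScene

__all__ = ["fit", "evaluate_model", "ablate", "ABLATION_VARIANTS"]


def _flip_scene(scene: GroundTruthScene) -> GroundTruthScene:
    # pixel centers sit at integers, so the mirror axis is (W-1)/2
    W = scene.image.shape[1]
    boxes = [BoundingBox(W - 1 - b.cx, b.cy, b.w, b.h) for b in scene.boxes]
    return GroundTruthScene(image=scene.image[:, ::-1].copy(), boxes=boxes,
                            scene_type=scene.scene_type, split=scene.split,
                            class_ids=list(scene.class_ids))


def fit(scenes: Sequence[GroundTruthScene], cfg: RunConfig,
        model: Detector | None = None, log=None
        ) -> tuple[Detector, list[LossComponents]]:
    """Train a detector on in-memory scenes; returns (model, per-epoch losses).

    All randomness (init, shuffling, flip augmentation) flows from
    ``cfg.seed``, so two runs with the same config produce identical weights.
    """
    if model is None:
        model = build_model(cfg.arch, seed=cfg.seed)
    model.train()
    rng = np.random.default_rng(cfg.seed + 1)
    opt = SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.sgd_momentum)
    state = WiouState(exponent=cfg.arch.wiou_exponent) \
        if cfg.arch.box_loss == "wiou" else None

    history: list[LossComponents] = []
    n = len(scenes)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        box_sum = cls_sum = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = []
            for k in idx:
                sc = scenes[k]
                if cfg.flip_augment and rng.random() < 0.5:
                    sc = _flip_scene(sc)
                batch.append(sc)
            comps, state = training_step(model, batch, state, opt)
            box_sum += comps.box_loss
            cls_sum += comps.cls_loss
            n_batches += 1
        epoch_comps = LossComponents(box_loss=box_sum / n_batches,
                                     cls_loss=cls_sum / n_batches,
                                     box_weight=comps.box_weight,
                                     cls_weight=comps.cls_weight)
        history.append(epoch_comps)
        if log is not None:
            log(f"epoch {epoch + 1:3d}/{cfg.epochs}  "
                f"box={epoch_comps.box_loss:.4f}  cls={epoch_comps.cls_loss:.4f}  "
                f"total={epoch_comps.total:.4f}")
    return model, history


def evaluate_model(model: Detector, scenes: Sequence[GroundTruthScene],
                   conf_threshold: float = 0.25, nms_iou: float = 0.5
                   ) -> MetricsReport:
    """Run inference on every scene and compute the metrics report.

    Detections are collected at a low confidence floor (0.02) so the PR curve
    and AP integrate over the full score range; the reported single-point P
    and R use ``conf_threshold``.
    """
    dets = [predict(model, sc.image, conf_threshold=0.02, nms_iou=nms_iou)
            for sc in scenes]
    return evaluate_detections(dets, scenes, conf_threshold=conf_threshold)


ABLATION_VARIANTS: dict[str, dict] = {
    "baseline": dict(use_dcn=False, attention="none", small_head=False, box_loss="ciou"),
    "+dcn": dict(use_dcn=True, attention="none", small_head=False, box_loss="ciou"),
    "+dpse": dict(use_dcn=False, attention="dpse", small_head=False, box_loss="ciou"),
    "+small_head": dict(use_dcn=False, attention="none", small_head=True, box_loss="ciou"),
    "+wiou": dict(use_dcn=False, attention="none", small_head=False, box_loss="wiou"),
    "all": dict(use_dcn=True, attention="dpse", small_head=True, box_loss="wiou"),
}


def ablate(train_scenes: Sequence[GroundTruthScene],
           eval_scenes: Sequence[GroundTruthScene],
           cfg: RunConfig, log=None) -> dict[str, MetricsReport]:
    """Train each architecture variant on the same data/seed and score it."""
    results: dict[str, MetricsReport] = {}
    for name, switches in ABLATION_VARIANTS.items():
        variant_cfg = replace(cfg, arch=replace(cfg.arch, **switches))
        if log is not None:
            log(f"[{name}] training ({variant_cfg.arch.strides} strides, "
                f"loss={variant_cfg.arch.box_loss})")
        model, _ = fit(train_scenes, variant_cfg)
        results[name] = evaluate_model(model, eval_scenes,
                                       conf_threshold=cfg.conf_threshold,
                                       nms_iou=cfg.nms_iou)
        if log is not None:
            log(f"[{name}] {results[name].summary()}")
    return results
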