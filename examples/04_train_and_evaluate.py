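"""Train the desk-scale detector on a small scene set and score it.

Uses fewer scenes and epochs than the full desk experiment so it finishes in
a couple of minutes; expect metrics well below the full run.  The full
experiment (200 scenes, 30 epochs) is what scripts/acceptance.py runs.
"""

from dataclasses import replace

import numpy as np

from aquadet import PROFILES, SceneSpec, generate_scene, predict
from aquadet.scenes import SCENE_TYPES
from aquadet.train import evaluate_model, fit


def mixed(n, size, seed0):
    rng = np.random.default_rng(seed0)
    return [generate_scene(SceneSpec(SCENE_TYPES[i % 5], size,
                                     int(rng.integers(2, 6)),
                                     seed=int(rng.integers(0, 2**31 - 1))))
            for i in range(n)]


cfg = replace(PROFILES["desk"], epochs=18)
train_scenes = mixed(80, cfg.arch.input_size, seed0=11)
held_out = mixed(15, cfg.arch.input_size, seed0=2**20)

model, history = fit(train_scenes, cfg, log=print)
report = evaluate_model(model, held_out)
print(f"\nheld-out: {report.summary()}")
print("(mAP50 = mean average precision at IOU 0.5; mAP50-95 averages over "
      "IOU thresholds 0.50:0.05:0.95)")

dets = predict(model, held_out[0].image, conf_threshold=0.25)
print(f"\nfirst held-out scene: {len(held_out[0].boxes)} fish, "
      f"{len(dets)} detections at confidence >= 0.25")
for d in dets[:5]:
    print(f"  score={d.score:.2f} center=({d.box.cx:.0f},{d.box.cy:.0f}) "
          f"size={d.box.w:.0f}x{d.box.h:.0f}")
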