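"""IOU-family box losses and dual-pooling channel attention on toy inputs."""

import numpy as np

from aquadet import (BoundingBox, SqueezeExciteParams, WiouState, ciou_loss,
                     dpse_excite, dpse_squeeze, iou, recalibrate,
                     update_wiou_state, wiou_loss)

pred = BoundingBox(cx=0, cy=0, w=2, h=2)
target = BoundingBox(cx=1, cy=1, w=2, h=2)
print(f"IOU(pred, target)        = {iou(pred, target):.4f}   (overlap 1, union 7)")
print(f"CIOU loss                = {ciou_loss(pred, target):.4f}   "
      "(adds center-distance + aspect penalties)")

state = WiouState()  # running mean 1.0, alpha=1.9, delta=3.0
print(f"Wise-IOU loss            = {wiou_loss(pred, target, state):.4f}   "
      "(distance attention x focusing coefficient)")
state = update_wiou_state(state, [0.4, 0.6])
print(f"running mean after batch = {state.mean_iou_loss:.4f}   "
      "(sliding average, momentum 0.99)")

# a high-quality pair (low IOU loss) is down-weighted by the focusing term
good = BoundingBox(cx=0.1, cy=0.1, w=2, h=2)
print(f"Wise-IOU for a near-perfect box = {wiou_loss(good, pred, state):.4f} "
      f"vs plain IOU loss {1 - iou(good, pred):.4f}")

rng = np.random.default_rng(3)
fm = rng.uniform(0, 1, size=(4, 6, 6))
fm[2, 3, 3] = 6.0  # one channel carries a sharp local feature
z = dpse_squeeze(fm)  # spatial mean + spatial max per channel
print(f"\ndual-pooling descriptor: {np.round(z, 2)} (channel 2 highlighted)")
params = SqueezeExciteParams.init(4, reduction=2, rng=rng)
s = dpse_excite(z, params)
print(f"channel weights in (0,1): {np.round(s, 3)}")
out = recalibrate(fm, s)
print(f"recalibration attenuates, never amplifies: "
      f"max |out|/|in| = {np.max(np.abs(out) / (np.abs(fm) + 1e-12)):.3f}")
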