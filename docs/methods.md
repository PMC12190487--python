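# Methods

`aquadet` is a desk-scale re-implementation of an underwater fish detector
built around four ideas: deformable sampling in the backbone, dual-pooling
channel attention in the neck, an extra fine-resolution prediction head for
small targets, and a dynamically focused IOU loss for box regression.  This
note records the model, the choices made where the design was genuinely open,
and what the synthetic experiments do and do not show.

## Tensor engine

All differentiable computation runs on a small reverse-mode automatic
differentiation engine over float64 numpy arrays (`aquadet.autodiff`).  It
provides broadcasting arithmetic, matmul, reductions, im2col-based 2-D
convolution, nearest-neighbour upsampling, a bilinear gather with gradients
to both the feature map and the sampling coordinates (the primitive behind
every deformable operator), a numerically stable weighted binary
cross-entropy, and SGD with classical momentum.  Gradients of every composite
op are checked against central finite differences in the test suite; float64
keeps those checks at relative error below 1e-3 (typically 1e-9).

## Deformable operators

A standard convolution samples a regular K = N×N grid: y(p0) = Σk wk ·
x(p0 + pk).  The deformable version adds a learned per-location displacement
Δpk to every sampling point and resolves the fractional positions with the
separable triangular kernel g(a,b) = max(0, 1−|a−b|); positions outside the
map contribute zero.  Offset fields carry 2K channels, k-major (Δy, Δx)
pairs, k row-major over the kernel grid.  The offset-generating branch is a
3×3 convolution initialized to zero, so a freshly built deformable layer is
exactly a standard convolution — the zero-offset equivalence is the
operator's main oracle and is also what makes swapping blocks into a trained
or freshly initialized network safe.

Deformable ROI pooling divides a half-open ROI into t×t subregions,
translates each by its own (Δy, Δx), samples an n×n interior grid per
subregion (default n = 2) and max-reduces.  Sample points are placed at
`edge − 0.5 + (i + 0.5)·side/n`, so a subregion whose side equals n pixels is
sampled exactly at its integer pixel centers and zero offsets reproduce plain
max pooling.  Inside the detector the operator appears as a
resolution-preserving stage: the whole feature map is one ROI with 1×1-pixel
subregions and a single center sample per subregion, which makes the
zero-offset case the identity map (the block-level equivalence above would
otherwise be broken by interior-grid smoothing).  Coordinates are (row, col),
0-based, pixel centers at integers.

## Channel attention

SE: squeeze by global average pooling (z_c = mean of channel c), excite by
s = σ(W2·relu(W1·z)) with a reduction-r bottleneck (default r = 16, bottleneck
width floored at 4), recalibrate by x̃_c = s_c·u_c.  The dual-pooling variant
adds the spatial maximum to the average — the max highlights sparse,
high-contrast texture that averaging washes out — and applies an extra sigmoid
to the combined descriptor before the bottleneck.  That inner sigmoid bounds
the descriptor to (0,1) and partially undoes the magnitude signal of the
avg+max sum; it is implemented as printed and can be disabled
(`inner_sigmoid=False`) for ablation.  The excitation layers carry no biases,
which keeps the zero-weight identity (all weights 0 ⇒ every channel weight
exactly 0.5).

## Box losses

Boxes are pixel-space center format (cx, cy, w, h); degenerate sides are
rejected, never clamped.  CIOU adds to the IOU loss a center-distance penalty
ρ²/c² (c the enclosing-box diagonal) and an aspect term αν with
ν = (4/π²)(arctan(wt/ht) − arctan(w/h))² and α = ν/((1−IOU)+ν) held constant
during differentiation.

Wise-IOU multiplies the IOU loss by a distance-attention factor
R = exp(ρ²/(cw²+ch²)) and a non-monotonic focusing coefficient r = β/(δ·α^(β−δ)),
where β is the outlier degree: the current IOU loss divided by a running
(momentum-0.99) mean of batch IOU losses, seeded at 1.0 and floored at 1e-4.
Quantities marked non-backpropagated — the attention denominator and β's
numerator — contribute values but no gradients (verified by finite
differences against a frozen-value reference).  Two exponent conventions for
r circulate; the default (β−δ) has the designed property r = 1 at β = δ, and
the alternative (β−α), seen in some statements of the method, is available
as `wiou_exponent="printed"`.  Defaults
α = 1.9, δ = 3.0 follow the original method's convention.

## Detector

Backbone: stride-2 stem, then four stages of (stride-2 conv → cross-stage
C2f block) producing pyramid levels P2–P5 at strides 4/8/16/32 with channels
(32, 64, 128, 256, 256)·width_mult, floored at 4.  With `use_dcn` the deepest
stage's C2f has deformable bottleneck convolutions (both layers) plus the
deformable pooling stage.  Neck: top-down only — upsample, concatenate with
the skip, C2f — with one attention block on the deepest feature and after
each merge (4 blocks with the small head, 3 without).  The second, bottom-up
aggregation pass of the full-scale design is omitted at desk scale; it adds
cost but no new operator.  Heads are anchor-free: per cell a 3×3 conv block
then a 1×1 conv to (tx, ty, tw, th, objectness, classes).

Decoding at stride s, cell (i, j):
`cx = (j + 0.5 + 4σ(tx) − 2)·s` and `w = (2σ(tw))²·2s`.  The ±2-cell center
range keeps targets assigned to neighbour cells well inside the responsive
part of the sigmoid, and the size scale puts each stride's design band
(max side in [s, 2s)) near σ ≈ 0.4, where gradients are largest.  Both
choices matter in practice: with a ±1-cell range neighbour targets sit at the
saturated edge of the sigmoid, and with a larger size coefficient
coarse-stride cells initialize far above their band and converge very
slowly.

Assignment: a stride-s grid is responsible for targets of max side s and
above, up to the decoder's representable cap of 8s, so each ground-truth box
is supervised at every scale in that window (large fish appear on the fine
grids too, where localization is most precise); boxes below the finest
stride fall back to the finest grid.  On each grid a box marks its center
cell and the two neighbour cells its center is offset toward positive;
contested cells regress the box whose center is nearest.  Two alternatives
were tried and rejected: a disjoint size-band rule (one scale per box)
starves the fine grids of large-object supervision, and a full
8-neighbourhood of positives turns every cell of the coarse 5×5 grid
positive in dense desk-scale scenes, leaving the objectness head no
negatives to learn from.  This static rule replaces the upstream
task-aligned assigner, which is out of scope.

Losses: the selected IOU-family loss over positive cells (mean), binary
cross-entropy objectness over all cells with positives up-weighted 16× and
supervised toward the detached IOU of their currently decoded box (so
confidence learns to rank well-localized boxes first), and per-class BCE on
positives.  Total = 5·box + 1·(objectness + class).  The final 1×1 head conv
initializes its objectness bias to −4, the usual low-prior trick: cells start
near-silent, so early optimization trains the boxes instead of suppressing a
flood of false positives.  There is no distribution-focal component: the
upstream head's DFL is undefined in the source design and is replaced by
this direct regression.

Inference: decode every cell, keep cells whose best class score
(σ(obj)·σ(cls)) clears the confidence threshold (0.25 reporting, 0.02 when
integrating PR curves), clip to the image, then greedy per-class NMS at IOU
0.5 with box voting: each kept detection's box is replaced by the
score-weighted average of the cluster it suppressed.  The grids emit several
near-duplicate boxes per object, often from different pyramid levels;
averaging these independent estimates measurably tightens localization.

## Synthetic scenes

Each scene is a blue-green vertical gradient plus smoothed low-frequency
noise, with parametric fish: an ellipse body (total length L, height
L/aspect) whose spine is bent quadratically (`bend` ∈ [0,1] displaces the tip
by up to L/4), a triangular tail, stripe texture, and an eye dot.  The tight
axis-aligned box of the drawn pixel support is the ground truth, clipped to
the frame; boxes are amodal — plant occluders drawn over a fish do not shrink
its box.  Scene types and their composition rules:

- `dense_occlusion`: subsequent fish are placed near an existing one;
  placements with pairwise box IOU above 0.6 are rejected and retried.
- `deformation`: bend sampled in [0.5, 1.0] (others use [0, 0.25]).
- `plant_occlusion`: 2–4 sinuous green strips drawn after the fish.
- `blur_lowlight`: Gaussian blur (σ 1.2–2.2 px) and brightness ×[0.4, 0.7].
- `small_targets`: fish 6–16 px long, 6–12 per image.

Fish lengths elsewhere are 12–28 % of the image side; 2–7 fish per image by
type.  Datasets are written as PNG + YOLO text labels + a tab-separated
manifest, split 70/15/15 by seeded shuffle (floor for val/test, remainder to
train).  Everything is byte-deterministic under the seed.

What the generator does not emulate: real water turbidity, fish appearance
variation beyond hue/texture noise, camera noise and perspective, motion
blur, and class diversity (a single "fish" class).  Passing the end-to-end
test therefore shows the pipeline can learn to localize deformable,
occluded, small, low-contrast objects it was built for — not that it reaches
any particular accuracy on real imagery.

## Evaluation

Detections are matched per image greedily in descending score; a detection
claims the highest-IOU unclaimed ground-truth box at or above the threshold.
AP integrates the monotone (non-increasing) precision envelope over recall
(all-point interpolation); mAP50 averages per-class AP at IOU 0.5, mAP50-95
over thresholds 0.50:0.05:0.95.  TP flags are pooled across images in global
score order.  True negatives are not defined for box detection and are never
used.  Single-point P and R are reported at confidence 0.25; the max-F1
operating point is also available, since printed P/R tables in the
literature rarely state their threshold.

## Problem sizes and profiles

The `desk` profile — 160-px input, width 0.25 (≈270 k parameters), batch 8,
30 epochs, SGD lr 0.03 with momentum 0.9, horizontal-flip augmentation, no
learning-rate schedule — trains on 200 synthetic scenes and evaluates on 50
held-out scenes in a few minutes on one CPU core; these are the package's
standard experiment sizes.  The desk profile regresses boxes with CIOU: its
additive center-distance and aspect penalties give useful gradients from the
first step, which matters in a 750-step budget, whereas Wise-IOU's
non-monotonic focusing is built to down-weight label noise over long
schedules — a regime the clean, exactly-labelled synthetic scenes never
enter.  Wise-IOU is the default of the full architecture configuration, is
trained by the `+wiou` and `all` ablation variants, and its algebra and
gradient-detachment contract are covered by the unit tests.  The `full`
profile records the full-scale settings (640-px input, batch 8, lr 0.01, 130
epochs) as documentation; it is not exercised by the tests.

## Known limitations

- The neck is top-down only; no bottom-up aggregation pass.
- One class; the classification head is exercised but trivially separable.
- The assigner is static (size bands + 8-neighbourhood), not task-aligned.
- Deformable blocks are used only in the deepest backbone stage by default.
- Running-statistics batch norm plus small batches means eval-mode outputs
  differ slightly from train-mode outputs early in training.
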