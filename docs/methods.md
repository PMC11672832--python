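# Methods

This note documents the models, conventions and design choices behind
`bcsyolo`, in the spirit of the methods sections that accompany
simulation and analysis packages.

## Problem setting

Automated body-condition scoring (BCS) of dairy cows from overhead 2-D
camera frames is framed as single-class-per-image object detection: each
frame contains one labeled tail-head region, and the detector must both
localize it and assign one of five ordinal condition classes (3.25,
3.50, 3.75, 4.00, 4.25 — the range observed in lactating herds; scores
outside it are rare on production farms). The engineering constraint is
deployment on farm-side hardware, so the package centres on three
lightweight mechanisms layered onto a standard one-stage anchor-free
detector (stem, four CSP-style C2f backbone stages, SPPF, PAN neck,
three-level head at strides 8/16/32):

1. **Star-operation feature blocks.** The star operation multiplies two
   linear transforms of the same feature element-wise. Writing the
   bias-augmented input as x ∈ R^{d+1}, (w1ᵀx)(w2ᵀx) = Σᵢ Σⱼ w1ᵢ w2ⱼ
   xᵢ xⱼ: the product carries every pairwise monomial of the input, a
   linear map into an implicit feature space of dimension
   (d+1)(d+2)/2 (the count of distinct monomials xᵢxⱼ with i ≤ j),
   obtained for the price of two pointwise convolutions and one
   multiply. The star block wraps this in a depthwise 7×7 convolution,
   two parallel pointwise maps (activation on one branch only; SiLU by
   default, ReLU6 available), a pointwise projection, a second
   depthwise convolution, and a residual connection. Replacing the two
   3×3 convolutions of the stock C2f bottleneck with a star block cuts
   the block's cost from 36c² to roughly (6e)c² multiply-accumulates
   per pixel at width c and expansion e.
2. **EMA attention.** Per channel group, features are average-pooled
   along width (z^H(c,i) = mean over j of x(c,i,j)) and along height
   (z^W(c,j) = mean over i of x(c,i,j)); the two descriptors are
   spliced along the spatial axis — H first, then W, a fixed part of
   the contract — passed through a shared 1×1 convolution and a
   sigmoid, split back, and applied multiplicatively in both
   directions. This directional gate is exposed on its own
   (`EMAGate`, `ema_variant="gate"`). The full cited module
   (`EMA`, `ema_variant="full"`) adds a parallel 3×3 branch and a
   cross-spatial softmax interaction between the two branches; it is
   the default inside the assembled model because the published
   compute budget of the EMA ablation (+1.1 GFLOPs over the star
   variant) is only reachable with the 3×3 branch present — the
   pooled-gate alone costs a few MFLOPs.
3. **Shared GroupNorm detection head (SSLDH).** Per level, a GroupNorm
   1×1 adapter brings P3/P4/P5 to one hidden width; a single shared
   stack — GroupNorm 3×3 conv, a star-style interaction of two 1×1
   "FC" maps combined by element-wise multiplication, a second shared
   GroupNorm 3×3 conv, and shared 1×1 regression/classification output
   convolutions — serves all three levels, with a learnable scalar per
   level on the regression branch to absorb stride-dependent distance
   ranges. GroupNorm normalizes within a sample, so head statistics are
   independent of batch size. Box regression is distribution-based
   (reg_max = 16 bins per side, decoded by softmax expectation).
4. **Channel-wise distillation (CWD).** Each channel of a feature map
   is softmax-normalized over its H·W spatial positions at temperature
   T; the loss is (T²/C) Σ_c KL(teacher_c ‖ student_c). The softmax is
   over space, so the loss transfers *where* a channel concentrates
   activation mass and is invariant to per-channel offsets. Teacher
   (s-scale) and student are hooked at the four neck fusion outputs,
   layers 12/15/18/21 of the canonical numbering; width mismatches are
   bridged by student-side 1×1 adapters that are trained jointly and
   dropped after training, leaving the deployed student unchanged.

## Tensor engine

All networks run on a small reverse-mode autodiff engine over NumPy
float32 arrays (`bcsyolo.nn`): grouped im2col convolution, max pooling,
nearest upsampling, BatchNorm/GroupNorm, SiLU/ReLU6/sigmoid, and SGD
with momentum, weight decay and global-norm gradient clipping. It is a
deliberate engineering choice that keeps the package pure-Python/NumPy
and CPU-deterministic; gradient correctness is pinned by
finite-difference tests. Two behaviours matter for reproducing results:

* **BatchNorm running statistics** use a cumulative (equal-weight)
  moving average, and `train()` ends with one statistics pass over the
  training images at the final weights (`recalibrate_bn`). Exponential
  running averages tuned for 10⁵-step schedules are badly calibrated
  after the few hundred steps of a desk-scale run; re-estimation at
  the final weights makes inference-mode normalization exact.
* A BatchNorm layer that has never seen a training batch falls back to
  batch statistics in inference mode (there is nothing learned to
  normalize with); this keeps freshly initialized teachers usable as
  frozen distillation references.

Head outputs are initialized to priors (classification bias at a low
object prior, distance-bin bias decaying with bin index) so short runs
do not spend their first epochs un-learning a uniform prior — standard
practice in the detector lineage this builds on.

## Architecture profiling conventions

Published budget numbers depend entirely on counting conventions, so
they are fixed here explicitly:

* **FLOPs** (per image, at a stated input size, 640 unless noted): one
  multiply-accumulate = 2 operations; a convolution costs
  2·k²·(C_in/groups)·C_out·H_out·W_out, plus one op per output element
  when a bias is present; max pooling costs k²−1 comparisons per
  output element; normalization is treated as folded into the
  preceding convolution, and activations/element-wise glue are
  excluded as negligible (well under 1% of the total).
* **Size**: the byte length of the saved checkpoint (an uncompressed
  NumPy archive holding the full state — weights and normalization
  statistics — plus a JSON record of the config, layer numbering and
  entry table) with arrays stored at half precision; MB means 2²⁰
  bytes.
* Two independent FLOP counters are kept: a hook-based counter that
  traces a real forward pass, and a closed-form counter that works
  from the config arithmetic alone. Tests hold them to within 1%.

Two block-level constants were fixed by calibrating the assembled
architectures against the published ablation budgets (8.2 / 7.0 / 8.1 /
6.5 GFLOPs and 5.94 / 5.05 / 5.20 / 3.98 MB for baseline / star /
star-EMA / full variant at n-scale, 5 classes, 640², and 28.7 GFLOPs /
21.4 MB for the s-scale teacher), values the published design leaves
unstated: the star-block expansion ratio (2.5) and the EMA group
count (4). With those fixed, all ten budget numbers are reproduced
within 2% with the head hidden width at its natural default (the P3
width, 64 at n-scale). The residual 1–2% gap on some entries is
consistent with serialization-container and counting-convention
differences between frameworks and is not tuned further.

## Synthetic data

The generator emulates the acquisition geometry of the farm setup, not its
photometric content: 1297×720 frames (the native camera resolution; a
scaled-down render keeping that aspect is used in tests), a textured
gray alleyway background with smooth clutter, and exactly one
elliptical "tailhead" object per image. The five ordinal classes are
driven by strictly monotone latents — ellipse aspect ratio 1.20→1.80,
central groove depth 0.10→0.58, and bump amplitude 0.30→0.62, each with
3–5% per-image jitter — together with global brightness jitter
(0.75–1.25) and pixel noise. Because class is a monotone latent,
confusions concentrate on adjacent classes, mirroring the ordinal
difficulty of real scoring. What the generator does *not* model:
cow-to-cow shape variation, occlusion, multiple animals, wet/soiled
coats, or realistic illumination fields. Passing smoke tests therefore
demonstrates that the training, evaluation and robustness machinery is
sound end-to-end — not that the detector would reach any particular
accuracy on farm data.

The per-category split assigns floor(ratio·n) images per class to
train and the remainder to validation (the published train/validation
totals are not an exact 80/20 of the published class counts, so the
rounding rule is documented rather than matched). Training images are
letterboxed (aspect-preserving, gray fill) to the square network input.

A classical matched-filter reference detector (`BlobDetector`) is
provided for harness checks that need a competent detector without a
training run: difference-of-Gaussians localization with moment-based
box sizing, and nearest-prototype classification on two
brightness-normalized contrast features, the prototypes self-calibrated
from a few clean renders per class. Its features live in fine contrast,
so motion blur degrades it smoothly — the property the blur harness
measures.

## Robustness harness

`blur_robustness_eval` draws a seeded fraction (default 20%) of the
validation images, convolves them in memory with a normalized line
kernel oriented along the travel direction (default horizontal; kernel
35 represents the moderate blur of a cow walking under the camera), and
reports paired clean/blurred detection metrics. Blurred images replace
the originals in the perturbed evaluation (they do not augment it), and
the on-disk dataset is never modified.

## Evaluation

Precision = TP/(TP+FP) and recall = TP/(TP+FN) from greedy one-to-one
matching per class at a stated IoU threshold (predictions in descending
confidence, each matching the highest-IoU unmatched truth of its
class). AP integrates the precision envelope over recall (all-points
interpolation); an 11-point mode is kept for comparability with older
protocols, but mAP@50:95 (mean over IoU 0.50:0.05:0.95, then over
classes) requires the all-points form, which is therefore the default.
Per-class P/R are reported at the maximum-F1 point of the IoU-0.5
sweep. Validation decoding uses a very low confidence threshold
(0.001) because AP depends on ranking, not on absolute scores.

## Desk-scale study sizes

All stochastic checks run at sizes chosen for a single CPU: renders at
324×180 (1297:720 aspect), network input 64–96 px, and short schedules
— a 5-epoch run on a 200-image dataset for the loss-decrease check, a
2-epoch run on a 500-image dataset for the class-distinguishability
check (validation mAP@50 must beat the 1/5 chance proxy), and 50
distillation steps on a fixed batch. The distillation smoke run uses a
large CWD weight (500) so the distillation term dominates the composite
objective; its descent — strictly decreasing 10-step window means — is
the observable. Per-step values still jitter because the detection
gradient and the evolving normalization statistics perturb individual
steps. The architecture profiles are exact and run at the full 640²
input.

## Known limitations

* The tensor engine is CPU-only and unoptimized beyond BLAS-backed
  im2col; full-scale (640², 100-epoch) training is out of its intended
  range.
* The detection loss uses a simple inside-box assigner with CIoU/BCE/
  DFL terms rather than a task-aligned assigner; adequate for smoke
  scale, not tuned for accuracy records.
* Checkpoint sizes depend on the archive container; a different
  serializer would shift the MB column by a few percent.
* The synthetic generator's single-latent class structure is far
  easier than real BCS imagery; reported smoke metrics must not be
  read as accuracy claims for real data.
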