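# Methods

## Problem and data model

A B-scan is a grayscale raster `x ∈ R^{C×H×W}` (C = 1 throughout) with
intensities in [0, 1]; the target is an integer label map of the same extent
with `K = 9` classes (background + eight retinal layers, anatomically ordered
top-to-bottom: NFL, GCL+IPL, INL, OPL, ONL+IS, OS, OPR, RPE) or `K = 10`
with an additional intraretinal-fluid class. Coordinates are (row, col),
0-based, origin top-left; serialization and patch order follow raster order
(left to right, top to bottom).

## Network

**Encoder.** Block 1 applies two stride-1 3×3 conv + batch-norm + ReLU
stages and then one stride-2 convolution; each subsequent block applies two
stride-1 stages followed by 2×2 max pooling that records per-window argmax
indices; the final block does not downsample. The default channel
progression is (32, 64, 128, 128), i.e. three spatial halvings, giving a
128-channel 32×32 bottleneck for a 256×256 input. Stage count and widths are
fully configurable (`ModelConfig.encoder_channels`); the skip feature of
each block is taken after its second stride-1 convolution.

**Bottleneck.** The bottleneck raster is cut into `p×p` patches (default
`p = 2`) in raster order and each flattened patch is multiplied by a
trainable embedding `E ∈ R^{p²c×d}` (default `d = 128`). `vit_blocks`
pre-norm transformer blocks follow (default 4), each
`x ← x + MHA(LN(x)); x ← x + MLP(LN(x))` with an `h`-head attention
(default 8) that splits the token width equally across heads. Per head the
Q/K/V projections are 2-D convolutions over the patch grid
(`attention_kernel`, default 3×3; 1×1 recovers a pure linear projection and
with it exact permutation equivariance of the stack, which the tests
assert). Attention is standard scaled dot-product with divisor `√d_h`,
`d_h = d/h`. No positional encoding is used. After the stack the tokens are
projected back to `p²c` and reshaped into a raster of the bottleneck's
size, which *replaces* the CNN bottleneck in the decoder (rather than being
concatenated with it). An optional class token (`use_class_token`, default
off) is prepended per the serialization convention and routed through the
attention via per-head linear paths, then discarded before deserialization —
the segmentation head never consumes it.

**Decoder.** The deepest stage refines the bottleneck with two 3×3
conv+BN+ReLU stages; each middle stage upsamples by index unpooling (values
written to the recorded argmax positions, zeros elsewhere), concatenates the
matching encoder skip, and applies two convolutions; the first-stage mirror
upsamples by a 2×2 stride-2 transposed convolution because the matching
encoder block downsampled with a strided convolution and left no pooling
indices. A 1×1 convolution maps to K channels; probabilities are the
per-pixel softmax.

**Initialization.** Kaiming fan-in normal for all convolution/linear
weights, zero biases, N(0, 0.02) for the class token, all drawn from a
single `numpy` generator seeded by `build_model(config, seed)`; two builds
from the same seed are bitwise identical.

## Loss

`L = α·L_ce + β·L_dice`, defaults `α = β = 0.5`.

* `L_ce = −(1/|Ω|) Σ_x Σ_l w_l g_l(x) log p_l(x)`: the sum over classes is
  averaged over pixels so magnitudes are independent of crop size. Class
  weights are proportional to inverse training-set frequency and rescaled to
  mean 1; a class absent from the training set receives the maximum
  present-class weight (with a logged warning) rather than a division by
  zero. Weights apply to the cross-entropy term only.
* `L_dice = mean_l [1 − 2Σ p_l g_l / (Σ p_l² + Σ g_l² + ε)]` over the
  classes present in the ground truth, computed on soft probabilities so it
  is differentiable; on hard predictions it reduces exactly to
  `1 − DSC`, which a test asserts against the metrics module.
* `ε = 1e-7` guards logs and Dice denominators.

The training path evaluates the cross-entropy through log-softmax of the
logits (numerically stable); the probability-space implementation is kept
for evaluation and is verified to agree.

## Metrics

Per-class one-vs-rest confusion counts; pooled accuracy; per-class
precision, recall and `DSC = 2TP/(2TP+FP+FN)`. A 0/0 score is reported as
NaN with an `undefined` flag and excluded from means — never silently
zero. Boundaries of a class are its pixels with a 4-neighbor of a different
class or on the raster edge; the Hausdorff distance between prediction and
truth boundaries is the two-way form `H = max(h(A,B), h(B,A))` with
Euclidean one-way distances (computed by `scipy`'s exact directed
routine and cross-checked against an all-pairs double loop in the tests).
The headline "mean HD" averages over non-background classes present in the
truth. Distances default to pixels; an optional `pixel_pitch` multiplier
converts to physical units, since no instrument calibration is assumed.

## Synthetic phantoms

The generator emulates the statistical structure of retinal B-scans, not
their optics. Each inter-layer boundary is the cumulative mean thickness
plus up to three random-phase low-frequency sinusoids with total amplitude
bounded by `boundary_smoothness`; a Gaussian bump subtracted near mid-width
compresses the inner layers into a foveal pit; ordering is enforced by a
running maximum, so thin layers may pinch to zero width at the fovea as they
do anatomically. Layer interiors get constant mean reflectivities
(bright NFL and RPE, dark nuclear layers); vessel shadows multiply all
intensities below the inner retina by `vessel_attenuation` inside
cosine-tapered vertical bands; speckle is multiplicative unit-mean gamma
noise with shape `1/speckle_level²` (the standard fully-developed speckle
model); optional fluid pockets are dark filled ellipses confined to the
outer-nuclear band and labeled with the dedicated class. Defaults
(128×128, speckle 0.25, two vessels, 10 px foveal dip) are a
moderate-difficulty condition chosen once to resemble bench SD-OCT data at
reduced resolution. Per-image seeds are `base + index`, recorded in the
dataset manifest so any single phantom can be regenerated.

What the phantoms do **not** model: depth-dependent SNR decay,
interferometric A-scan formation, motion artifacts, real pathology variety,
or the texture correlations of true speckle. Passing the benchmarks
therefore demonstrates that the implementation can learn and localize
layered structure under noise and shadowing — not clinical-grade
performance on real scans.

## Data pipeline and training

Slicing draws `n_slices` random distinct crop origins of a square window
(default 256) and then greedily adds grid-anchored crops until every
labeled pixel of the source is covered, satisfying both stated slicing
principles (distinct origins; full coverage). Photometric augmentation is
`clip(a·x + b, 0, 1)` with `a ∈ [0.8, 1.2]`, `b ∈ [−0.1, 0.1]`; random
erasing fills one rectangle (area 1–5% of the crop, aspect 0.3–3,
probability 0.5) with the crop mean to mimic a vessel shadow rather than
dropout. Augmentations never touch label maps. Cross-validation is a
balanced k-fold (default k = 5, 4:1 train/validation) assigned at the
source-image level so crops of one scan never straddle folds.

Training uses Adam with bias correction (lr 0.001, β1 0.9, β2 0.999,
ε 1e-8), batch size 8, 50 epochs, constant learning rate, no early
stopping; the deployed checkpoint is the epoch with the highest pooled
validation pixel accuracy, earliest epoch winning ties. Gradient clipping
is available but off by default. A non-finite loss aborts with the epoch,
batch and loss components. Training is deterministic given the seed.

## Desk-scale benchmark experiments

Two standard experiments (`octseg.experiments`) exercise the full stack at
sizes chosen for a single CPU; the acceptance script and the acceptance
tests run these exact definitions.

* **Memorization check** — a deliberately tiny network (channels 8/16/32,
  32-wide 2-block transformer, 4 heads) must overfit two 64×64 phantom
  crops to ≥ 99% training pixel accuracy within 200 full-batch Adam steps.
  The step size for this check is 5e-3: memorizing two fixed crops in 200
  steps warrants a larger step than the full training default, which
  reaches ~95% in the same budget.
* **Generalization benchmark** — a compact model (channels 16/32/64/64,
  64-wide 2-block transformer, 4 heads, patch 2) is trained for 10 epochs
  at batch size 1 and lr 2e-3 on 32 generator-default phantoms and
  evaluated on 8 held-out phantoms; foreground DSC, pooled accuracy and
  mean boundary HD are averaged over 3 independent seeds. Batch size 1
  maximizes optimizer steps (320) inside the fixed epoch budget, and the
  extra encoder halving gives the receptive field needed to suppress
  isolated misclassifications — the two-way Hausdorff distance is maximally
  outlier-sensitive, so a single stray blob of mislabeled pixels dominates
  it long after Dice overlap has saturated. Epoch-wise augmentation was
  evaluated for this benchmark and rejected: within 320 steps it slows
  convergence enough to worsen boundary agreement.

## Numerical choices and degenerate inputs

* The autodiff engine (`octseg.nn`) is float32 end-to-end during training;
  convolution uses im2col/col2im with a no-copy fast path for 1×1 kernels;
  batch/layer normalization are fused single ops so the graph retains only
  the normalized output and inverse standard deviation. All hand-derived
  backward passes are tested against central finite differences.
* Pooling is fixed 2×2/stride 2; window-local argmax indices (0–3) are what
  unpooling consumes, and the round trip is tested exactly on rasters with
  unique window maxima.
* Geometry is validated up front: input extents must be divisible by
  `2^(halvings)` and the bottleneck by the patch size; violations raise
  errors naming the required divisibility rather than silently padding.
* Empty boundary sets make the Hausdorff distance an error, not a zero;
  classes missing from a prediction contribute NaN to mean HD and are
  excluded.
* Batch-norm running statistics (momentum 0.1) serve evaluation mode, so
  inference is deterministic and batch-independent.

## Known limitations

* Plain two-way HD (not HD95) is reported, by design; users comparing to
  literature that reports percentile variants should expect larger values.
* Per-class region boundaries are evaluated, not named inter-layer
  interfaces; an interface-based HD would be a natural extension.
* The transformer's memory grows quadratically in token count; large
  inputs with small patches are CPU- and memory-hungry.
* No pre-training is used or supported anywhere; the design targets small
  datasets from scratch.
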