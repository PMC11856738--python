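# Methods

## Problem and model

The package segments a single bright organ (the prostate on T2-weighted
MRI) from rank-3 scalar volumes with anisotropic voxel spacing. The model
is a 2D encoder–decoder convolutional network operating on axial slices,
following nnU-Net conventions: two conv(3×3)–instance-norm–leaky-rectifier
blocks per resolution stage, strided-conv downsampling, transposed-conv
(kernel = stride = 2) upsampling, channels doubling from `base_channels`
(default 32) to a `max_channels` cap (default 320), and a 1×1
class-projection head at every decoder scale. The default 8-stage topology
takes 512×512 slices down to 4×4 at the bottleneck, giving 7 decoder steps.

Two components are the method's contribution:

**Context-modeling (CM) block.** At a decoder scale with features
`f_sf ∈ R^{HW×C}` and head logits `z ∈ R^{HW×2}`, the block computes

1. per-position class probabilities `D = softmax(z)` over the 2 classes;
2. per-class region representations `R_l = Σ_i (D_il / Σ_j D_jl) f_sf,i`
   — the spatially normalized, probability-weighted average of the
   features ("Nor" applied over space);
3. the per-position redistribution `f_seg,i = Σ_l D_il R_l`;
4. attention `W = row-softmax(f_sf f_segᵀ / C)` — the printed scaling is
   1/C, not 1/√C; a `sqrtC` option exists but is off by default;
5. the aggregated context `R_sf = W f_sf`, merged back by concatenating
   `[R_sf, f_sf]` along channels and compressing 2C → C with a learned
   1×1 convolution.

A CM block sits at every decoder step except the final full-resolution
one; `n_cm_modules` (default 6) counts insertions from the deepest step
upward. With the 8-stage default all six non-final decoder steps carry
one. The block needs per-scale logits, so a projection head exists at
every decoder scale; deep-supervision *losses* use only the heads above
the two lowest-resolution network stages, with weights halving per scale
and normalized to sum to one.

**FIFO memory bank.** A fixed-capacity queue (default m = 64) of
dataset-level feature maps at the bottleneck scale. Retrieval pools each
feature map spatially into a C-vector descriptor and ranks bank entries
by cosine similarity, ties broken toward the older (lower-index) entry.
The three best entries are concatenated with the current features (4C
channels) and compressed back to C by a learned 1×1 transform δ; until
the bank holds three entries the missing slots repeat the current
features, and an empty bank degenerates to the features alone. Once per
training batch the batch-mean fused map is pushed, detached from the
gradient tape; when capacity is exceeded the oldest entry is popped. The
bank is frozen at inference, so evaluation is deterministic. Where the
method description is ambiguous about which entry is popped, the module's
name (first-in-first-out) is taken literally.

## Objective and schedule

The loss is the equally weighted sum of a batch-averaged soft Dice loss,

    L_dice = −(2/K) Σ_k (Σ_i u_ik v_ik) / (Σ_i u_ik + Σ_i v_ik + ε),

with the class sum over all K = 2 classes (background included), and the
mean per-pixel cross-entropy on probabilities clipped at 1e-7. The printed
Dice form carries no smoothing term; ε = 1e-5 is added to the denominator
only, so a class absent from both prediction and target contributes 0
rather than 0/0. As a consequence the perfect-prediction value is −1
within ~5e-6 rather than exactly.

Optimization is SGD with Nesterov momentum 0.99, default schedule 1000
epochs × 250 iterations, batch 12 (2D), and a per-epoch poly learning-rate
multiplier `(1 − epoch/epoch_max)^0.9` (no intra-epoch decay; the schedule
is only defined per epoch). One seed drives phantom sampling, parameter
initialization and batch sampling. Parameter initialization uses separate
random streams for the backbone, the CM blocks and the bank fusion, so the
ablation baseline (`use_cm = use_mb = False`) is bit-identical to the
plain backbone under the same seed.

## Preprocessing

Volumes are resampled to a fixed target spacing, default
[0.66 × 0.66 × 5] mm (kept as printed in the source recipe, which calls
this target "isotropic" although it is not), with
`shape_k = round(shape_k · spacing_k / target_k)`. Images use an order-3
spline in plane and nearest-neighbour along the slice axis — with ~5 mm
through-plane spacing, smooth interpolation between slices would invent
structure; masks are nearest-neighbour on every axis. Z-score
normalization uses whole-volume statistics (per-volume, not
foreground-restricted). Axial slices are symmetrically padded/cropped to
the configured size (default 512); the 3D path crops a patch (default
320×320×16) centred on the mask centroid. The reference network is 2D;
3D patching is supported by the pipeline but no 3D network variant is
provided.

## Synthetic phantoms

The generator emulates the features of prostate T2W data that the method
targets, not MR physics: a bright ellipsoid (intensity 1.0) on a darker
background (0.3), anisotropic spacing [0.66, 0.66, 5] mm, per-seed jitter
of the semi-axes (±20%) and centre, additive Gaussian noise (σ = 0.05),
and an in-plane Gaussian boundary blur whose width ramps linearly from
σ = 0.5 voxels at the central occupied slice to σ = 2.5 voxels at the
first/last occupied slices — the apex/base analogue. The mask is the
clean ellipsoid, so ground truth is exact. Default semi-axes
(12, 10, 12.5) mm fit the 64×64×12 default grid. What passing tests on
phantoms shows: the architecture, loss, schedule and metrics interoperate
and can fit a bright-organ segmentation task to high DSC. What it does
not show: performance on real anatomy, multi-organ contrast, bias fields,
motion, or inter-scanner variation — none of which are simulated.

## Problem sizes used for verification

The package's own desk-scale configuration (`scaled_preset`) is a 4-stage
network with base 16 channels, a 16-entry bank, 64×64 phantom slices, and
20 epochs × 50 iterations at batch 4 — small enough to train in minutes
on one CPU while exercising every component (the 4-stage net carries CM
blocks at both of its non-final decoder steps). Held-out evaluation on 40
phantoms (24/8/8 train/val/test) reaches DSC above 90%. Batch 4 (rather
than the full recipe's 12) is part of this scaled problem size.

## Numerical choices

* Distances are reported in voxel units by default (`units="mm"` weights
  coordinates by spacing): the reference results tabulate ASSD/HD95 in
  voxels.
* Boundary extraction uses 6-connectivity (face adjacency); outside the
  grid counts as background. HD95 uses the linear-interpolation
  percentile over the directed-distance list; the brute-force oracle in
  the tests applies the same rule.
* Empty predictions: overlap metrics score 0%, distance metrics are
  reported missing (NaN) with a warning and excluded from aggregate
  means. Aggregates are arithmetic per-case means; a pooled
  (voxel-count-weighted) overlap variant is provided separately.
* Attention logits are scaled by 1/C as printed; softmax is row-wise
  (each query position's weights normalize to 1).
* Bank similarity scores are computed in double precision with per-row
  dot products: BLAS matrix-vector kernels can give bitwise-different
  results for identical rows, which would break deterministic
  tie-breaking.
* The autodiff engine computes convolutions by explicit im2col + GEMM;
  gradients of every operation are verified against central finite
  differences in the test suite.

## Known limitations

* No transformer baselines, no multi-GPU or mixed-precision training, no
  5-fold cross-validation orchestration, no DICOM ingestion, and no
  multiparametric (T1W/DWI/DCE) channels.
* The full-resolution attention of the CM block is quadratic in HW; at
  the published 512×512 resolution the deepest stages are cheap but a CM
  block at large HW is computationally prohibitive — one reason the final
  decoder step carries none.
* The NumPy engine is single-device and optimized for the desk-scale
  configuration, not for the full 1000-epoch recipe.
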