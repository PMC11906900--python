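# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, which parameters matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Problem and pipeline

The task is 3-class semantic segmentation of 3D µCT scans of mouse tibiae:
background (0), cortical bone (1), trabecular bone (2). Arrays are indexed
`(x, y, z)` with `z` the long bone axis; spacing is carried in µm and metric
output is converted to mm. The pipeline is: preprocessing → (training with
live augmentation) → sliding-window prediction → morphological
postprocessing → DSC/HD95 evaluation, with scans optionally split into 10
contiguous z-subsets for reporting (remainder slabs go to the proximal end;
the rule is otherwise arbitrary and only affects bookkeeping).

## Preprocessing

Otsu thresholding runs on an 8-bit min–max rescaled copy over a 256-bin
histogram so the safety margin `M = 5` has the fixed meaning of five grey
levels; the threshold convention is pinned (candidate `t` splits `[0,t)`
from `[t,255]`, the mask keeps voxels `≥ t − M`, ties take the smallest
`t`). The margin protects faint trabecular voxels. Cleanup retains the
largest 26-connected 3D component (removing holder, resin and free-floating
structures) and then removes the second-largest 8-connected component in
every z-slice (the fibula) — implemented literally as "the second largest";
a slice with three or more foreign components keeps the smaller ones, which
is flagged as a limitation. Component-size ties break on the smallest
minimum linear voxel index (deterministic, seed-free). Autocropping keeps a
configurable margin (default 8 voxels) around the bone bounding box and
fills off-mask voxels with the volume minimum rather than zero so the
subsequent z-scoring (population σ, over all voxels of the cropped volume)
is not distorted by an arbitrary fill value.

## Augmentation

Five families, each applied independently with probability `p = 0.1` per
sample, in a fixed order (affine, elastic, noise, intensity, contrast),
reproducible from the generator state. Rotation is about `z` only, angle
`U[0, π]`, with isotropic scale `U[0.85, 1.25]`; images resample
trilinearly, labels nearest-neighbour, under one shared transform. The
elastic deformation is the literal formula `x' = x + α·G(σ)` with the
per-axis field smoothed at `σ ~ U[9, 13]` voxels and `α ~ U[0, 900]`: the
smoothing shrinks unit noise by roughly `(4πσ²)^{-3/4}`, so even the largest
`α` produces displacements of a few voxels — a realistic warp. (An
alternative reading, normalising the field so `α` is the maximum
displacement in voxels, would displace crops by hundreds of voxels and was
rejected.) Gamma contrast operates on a min–max `[0,1]`-rescaled copy and
restores the original range, because the power map is undefined for the
negative intensities of z-scored data. Out-of-bounds voxels after geometric
transforms are filled with the image minimum / background label.

## Architecture

The hierarchy ledger for input `(H, W, D)` with embedding width `C` and
reduction `E`: stage `s ∈ {0..2}` has `C·2^s` channels at
`(H/(E_x·2^s), W/(E_y·2^s), D/(E_z·2^s))`; the bottleneck holds `8C`
channels (for the published `C = 96`, `E = [4,4,4]`, input `320×320×32`:
embedding `(96, 80, 80, 8)`, bottleneck `(768, 10, 10, 1)`).

Choices the description leaves open, and what this package does:

* **Window size** `(4, 4, 2)` with shift = half window per axis; symmetric
  zero padding when a stage extent is not a window multiple. Learned
  per-head relative position bias, standard shifted-window masking with
  cyclic shifts.
* **Branch vs. fusion downsampling**: each branch resamples itself (CACM's
  final stride-2 convolution; a stride-2 convolution after the Swin pair),
  and the TCFFM's "downsampling convolution" is read as the channel-halving
  1×1×1 fusion convolution. Both readings produce the documented stage
  shapes.
* **Attention gates** take their keys/values from the encoder fusion outputs
  (the patch embedding at the finest level) at all three decoder levels, and
  run their single cross-attention layer within the same local windows as
  every other non-bottleneck transformer block; a `window=None` switch
  restores global gating. Gate outputs are added to the encoder residual
  skip, as the architecture description states.
* **Patch embedding / head**: an axis factor 4 is two stride-2 3×3×3
  convolutions, a factor 2 one stride-2 convolution (z applied first on the
  way down), each followed by normalisation and GELU. The embedding and head
  use **instance norm** (per-channel over space): a cross-channel layer norm
  would subtract the per-position channel mean and destroy the absolute
  intensity level that voxel classification depends on; instance norm
  preserves per-voxel contrasts, the standard choice in segmentation
  backbones. The head mirrors the embedding with transposed convolutions at
  twice the branch width (2C) whose kernels are twice their stride
  (cropped), so neighbouring coarse cells overlap and sub-cell structure is
  reconstructable, then a 1×1×1 convolution to the class logits. With
  kernel = stride each output voxel would see exactly one coarse cell and
  thin trabecular struts could not be reconstructed at any training budget.
* MLP ratio 4, GELU, pre-norm LayerNorm inside transformer blocks; no
  dropout, no deep supervision.

### Initialisation

Three coordinated choices make the published optimizer protocol (SGD,
momentum 0.99, cosine schedule from 1e-4) effective at short CPU-scale
budgets; all are inert for long runs.

1. **Small-scale convolutions.** Backbone convolution kernels start at
   He/30. Each is followed by a normalisation layer, so the network function
   is invariant to their scale while their effective SGD learning rate grows
   as `1/‖w‖²`. At standard He scale the protocol moves weights by only
   ~0.2 in total over a 200-step run — far too little to form sharp class
   boundaries (even a 6-parameter logistic readout of raw intensity fails
   under it). Normalisation gains are never rescaled (GELU follows them, so
   they are not scale-invariant).
2. **Logit gain.** The output convolution starts at σ = 0.5/γ and its
   logits are multiplied by a fixed γ = 200, which raises the gradient
   scale (hence learning speed) of the final readout by the same factor
   while keeping initial logits O(1).
3. **Structured resampling init.** The first embedding convolution starts
   as a space-to-depth rearrangement (channel *i* samples voxel offset *i*
   of its stride cell) and the head's first transposed convolution as the
   matching depth-to-space inverse, so the freshly built network computes a
   monotone per-voxel transform of the input intensity. The high-gain
   output layer can then learn the intensity-threshold structure of the
   task within tens of steps, and the rest of the network refines from a
   sensible operating point.

The transformer linear layers use truncated-normal σ = 0.02 (already in the
fast-rotation regime; the blocks start near identity through their residual
paths).

## Training and inference

SGD with classical momentum 0.99 (no Nesterov, no weight decay — neither is
specified), batch size 4 (configurable down for CPU runs), random
`(320, 320, 32)` crops (smaller volumes are padded symmetrically), cosine
annealing `lr(t) = ½·lr₀·(1 + cos(πt/T))` from `lr₀ = 1e-4` to 0.
"Until convergence" is operationalised as early stopping on the validation
mean foreground Dice (patience 10 validations, one validation per
250-step epoch by default). Whole volumes are predicted by sliding windows
with 50% overlap and separable Hann-weighted blending of softmax maps
(weights floored at 1e-3 so edge voxels keep support); padding uses the
volume minimum and padded regions are discarded.

The scan-level split is 70/10/20 by `round(N·ratio)` with the remainder
absorbed by the training set, deterministic under a seed; all z-subsets of a
scan stay on one side of the split.

## Loss and metrics

Soft Dice is computed per foreground class with smoothing ε = 1e-5 in
numerator and denominator, then averaged; cross-entropy is the multi-class
mean of `−log p` at the true class (probabilities clamped at 1e-12). The
combination is `0.5·Dice + 0.5·CE`.

Hard DSC uses per-class binarisation; two empty masks score 1, one empty
mask 0. HD95 extracts boundary voxels (any 6-neighbour outside the mask,
array borders count as outside), computes spacing-scaled Euclidean distances
via exact distance transforms, and reports the **maximum of the two directed
95th percentiles** — the prevailing benchmark convention; the pooled variant
(95th percentile of both directed sets concatenated) is available under
`direction="pooled"`. Reported in mm.

## Postprocessing

Order: largest-foreground-component noise removal → endosteal smoothing →
trabecular reconnection; each stage can be disabled. Structuring elements
are discrete Euclidean balls. Endosteal smoothing opens the cortical mask
with radius `K_o = 3` and relabels removed voxels as trabecular, conserving
bone voxel count exactly; the erosion treats out-of-volume as bone so the
tube is not eaten where the ROI clips it. Reconnection closes the trabecular
mask with radius `R_c = 1`, taking bridge voxels from background only —
cortical voxels are never altered (the conservative reading of how closing
should interact with the other class).

## Phantoms

The generator emulates what the pipeline must survive: a tapered hollow
cortical shell; a trabecular lattice from a thresholded Gaussian random
field in the medullary cavity; a thin trabecularised endosteal lining that
anchors the lattice to the shell in every slice and makes it one connected
structure; a fibula rendered at bone intensity but labelled background and
spatially disconnected from the tibia (the proximal ROI lies above the
tibio-fibular junction), so preprocessing — not the generator — must remove
it; a holder bar and resin background at low intensity; additive Gaussian
noise (default σ = 8 on an 8-bit-like scale, keeping classes separable but
non-trivial). The lattice is closed with a radius-1 ball as its connecting
step, so the ground truth is stable under the reconnection operator. The
threshold is re-aimed a few times so the realised trabecular volume fraction
lands within 0.01 of the target (default 0.25); fractions below the lining
ring's own fraction (~0.13) are not reachable. Degradation modes (cortical
porosity, cortical thinning, trabecular sparsification/densification)
emulate treatment effects by exact-count random edits with consistent
intensity updates.

Per-slice anchoring is deliberate: it guarantees that the literal
"remove the second-largest 2D component" fibula rule can never delete true
bone on phantoms, making the 100%-recall property well-defined. Real
cross-sections do show free-floating trabecular islets; robustness of the
fibula rule to such data is outside what the phantom suite can demonstrate.
Phantoms also do not emulate growth plates, beam-hardening, ring artefacts,
or calibrated attenuation values, so passing tests show pipeline
correctness, not clinical-grade accuracy on real scans.

## Desk-scale sanity check

The learning check trains the tiny configuration (C = 8, heads (1,2,4,8),
window (4,4,2), E = (2,2,2)) on one fixed preprocessed phantom crop of
64×64×32 voxels for at most 200 steps under the published optimizer
protocol, evaluating every 10 steps from step 50 and stopping once the
foreground mean DSC reaches 0.9 (typical runs cross 0.9 within 60–140
steps and reach 0.90–0.95). `E = (2,2,2)` is used here because at
C = 8 a larger reduction makes the stage-0 code an information bottleneck
(8 channels describing a 32-voxel cell), capping achievable trabecular
detail regardless of optimisation; with 8-voxel cells the embedding can be
near-lossless. Problem sizes throughout the test-suite (phantom shapes
80–96 voxels across, 8³ metric-oracle masks, 200 training steps) are chosen
so the whole suite runs on a single CPU core in minutes.

## Known limitations

* The numbers reported by the original study (average DSC ≈ 0.98 on control
  scans after multi-GPU training on 74 high-resolution scans) are not
  reproducible at this scale and are not targets of the test suite.
* The NumPy autodiff core is single-threaded and eager; it is sized for the
  tiny configuration and for shape-level checks of the full one, not for
  production training of C = 96 models.
* The fibula-removal rule is implemented literally (exactly one component
  removed per slice); whether all non-largest components should go instead
  is left to review.
* Whether z-scoring should use bone-mask voxels only is open; all voxels of
  the cropped volume are used.
* "Avg" metric columns can average classes-then-subsets or pool subsets
  first; both orders are exported (`records_to_table`).
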