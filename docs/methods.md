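# Methods

## Problem and model

Masked-autoencoder (MAE) pre-training hides a large fraction of an image's
patches and trains a transformer to reconstruct them from the visible rest.
With the usual *uniform* random masking on 3D brain MRI, the visible 25% of
patches is scattered over the whole head, including large background and
low-information regions. `priormae` implements an *anatomical prior-informed*
alternative: the probability that a patch is kept visible is proportional to
how often tumor occurs in the brain structures it covers, so pre-training
concentrates on regions relevant to downstream tumor segmentation.

The pipeline has four statistical/algorithmic stages plus the model itself:

1. **Occurrence statistics.** Binary tumor label maps, co-registered to a
   common space, are summed voxelwise into occurrence counts `f_ij` (voxel
   `j` of parcellation region `R_i`). The parcellation-averaged sampling
   probability per region is

   ```
   P_Ri = Σ_j f_ij / ( V_Ri · Σ_i Σ_j f_ij )
   ```

   where `V_Ri` is the region volume. With voxel volume 1 this satisfies the
   conservation law `Σ_i P_Ri · V_Ri = 1` exactly. Counts on background
   (atlas label 0) are excluded from both numerator and grand total —
   including them would break the conservation law. A transcription of the
   published 128-region ET/TC/WT occurrence table (per-mille units, SRI-24
   space) ships with the package as reference data.

2. **Weight map.** `P_Ri` is broadcast over every voxel of its region,
   giving a voxelwise weight volume `W` that is constant within regions and
   zero on background. Units (fraction vs per-mille) are recorded but
   irrelevant downstream because sampling renormalizes.

3. **Patch probabilities.** Image and weight map are center-cropped to
   128³ (default), tiled into non-overlapping 8³ patches (n = 16³ = 4096
   tokens), and each patch gets probability
   `p_i = Σ_j w_ij / Σ_ij w_ij`.

4. **Visible-set sampling.** `k = round((1 − masking_ratio) · n)` distinct
   visible patches are drawn by *sequential weighted draws without
   replacement*: after each draw the weight vector is renormalized over the
   remaining indices. At the default masking ratio 0.75 this keeps exactly
   1024 of 4096 tokens. Marginal inclusion probabilities under this scheme
   differ from `p` itself; the tests pin them against exact enumeration of
   all ordered draws for n ≤ 6. With a flat weight vector the scheme
   reduces draw-for-draw to uniform sampling without replacement, which is
   also how the `random` baseline strategy is implemented — so the
   uniform-prior and random strategies produce bitwise-identical training
   trajectories under shared seeds (a tested invariant).

## Model and losses

* **Patch embedding** flattens each visible patch (8³ voxels × channels)
  and applies a learnable linear tokenizer plus a sinusoidal positional
  encoding `PE(pos,2i) = sin(pos/10000^(2i/D))`, `PE(pos,2i+1) = cos(·)` at
  the patch's *original* grid position. Positions are 0-based by default
  (a flag restores 1-based indexing); patch enumeration is row-major over
  the grid axes, fixed because the encodings depend on it.
* **Encoder**: 12 pre-norm transformer blocks, feature dimension D = 384
  (defaults). The blocks use standard multi-head self-attention with an
  optional windowed mode that restricts attention to contiguous token
  chunks; the exact linear shifted-window attention of the original
  architecture is out of scope, and nothing downstream depends on attention
  internals.
* **Decoder**: an explicit linear projection to the decoder width (applied
  even when the widths agree), one shared learnable mask token inserted at
  every masked position, positional encodings for all n tokens, 8
  transformer blocks, and a linear head predicting raw voxel intensities —
  predictions are emitted for *all* n positions.
* **Reconstruction loss** `L_Rec = ½ Σ_masked ‖ŷ_i − x_i‖²` is computed
  over masked positions only; its gradient with respect to visible-position
  predictions is identically zero (tested numerically). Targets are raw
  intensities, not per-patch-normalized values.
* **Adversarial loss.** A five-layer convolutional least-squares
  discriminator (four k=3 blocks, one k=1 head, spatial average) scores
  individual patches. Discriminator objective:
  `L_Adv(D) = ½ Σ_i (‖D(x_i) − 1‖² + ‖D(ŷ_i)‖²)` over all n patches, with
  reconstructions detached. The generator side is the least-squares fool
  term `L_Adv(G) = ½ Σ_i ‖D(ŷ_i) − 1‖²`, chosen to match the L2 style of
  the discriminator objective. Total: `L = L_Rec + λ·L_Adv(G)` with λ = 1
  (λ = 0 recovers the plain MAE objective). Training strictly alternates
  one discriminator and one autoencoder AdamW step per batch.
* **Downstream segmentation.** The pre-trained tokenizer and encoder are
  kept; decoder and discriminator are discarded. When the fine-tuning input
  has more channels than pre-training (4-modal MRI vs single T1), only the
  tokenizer is re-initialized; the transformer blocks transfer. Token
  features tapped after encoder blocks 2, 4, 6, 8, 12 (configurable) plus
  an image-level convolutional feature z₀ feed a lightweight decoder built
  from residual conv blocks, stride-2 downsampling convs, and kernel-2
  stride-2 transposed-convolution upsamplers. It emits 3-channel logits
  (WT/TC/ET) at four resolutions (full, ½, ¼, ⅛ per axis), trained with
  `L_Seg = Σ_{i=1..4} (1/2^{i−1}) · (CE(S_i, Ŝ_i) + Dice(S_i, Ŝ_i))`,
  ground truth resized by nearest-neighbor. Because WT ⊇ TC ⊇ ET are
  overlapping classes, the cross-entropy term is per-channel binary
  cross-entropy with sigmoid activations (softmax CE would be ill-posed on
  non-exclusive channels); the Dice term is the soft Dice loss averaged
  over channels.

## Numerical engine

All neural components run on a small reverse-mode automatic-differentiation
engine written for this package (`priormae.nn`): float64 tensors over numpy,
tape-based backward, with linear, layer-norm, attention, 3D convolution and
transposed-convolution primitives, and decoupled-weight-decay AdamW. Every
primitive's gradient is tested against central finite differences. The
engine is sized for desk-scale models; it is single-threaded apart from
BLAS and makes no attempt at GPU execution or mixed precision.

## Synthetic study fixtures

The fixture generator emulates the structure the statistics need, not MRI
physics:

* **Atlas**: a seeded Voronoi partition (Euclidean distance, ties to the
  lowest region id) of a brain mask — an axis-aligned ellipsoid inscribed
  at 90% of each half-extent, or the full grid. Regions are contiguous,
  nonempty, variable-size; requesting more regions than mask voxels is an
  error.
* **Tumor labels**: each voxel of region i is tumor-positive independently
  with a configurable per-region Bernoulli rate; background is never
  positive. A single binary class is the default; nested TC/WT-style
  classes are available through rate multipliers applied to a shared
  uniform draw per voxel, which enforces nesting by construction.
* **Intensities**: per-region mean levels (uniform in [0.5, 1.5]) plus iid
  Gaussian noise; background 0.

One root seed feeds fixed per-operation sub-streams (0 atlas, 1 tumor,
2 intensity, 3 auto-rates), so the three generators are independently
reproducible. What these fixtures do *not* model: registration error,
multi-modal contrast, bias fields, anatomically shaped tumors, or
inter-subject variability — so passing tests demonstrate correctness of the
statistics, sampling and optimization machinery, not segmentation quality
on real data.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| masking ratio | 0.75 | fraction of patches hidden from the encoder |
| patch size | 8 voxels/axis | token granularity (4096 tokens at 128³) |
| crop size | 128 | center-crop side before patchification |
| D / decoder dim | 384 / 384 | token feature widths |
| encoder / decoder layers | 12 / 8 | transformer depths |
| optimizer | AdamW, lr 1e-3, wd 5e-2 | pre-training recipe |
| batch size / epochs | 12 / 300 | full-scale pre-training recipe |
| adversarial weight λ | 1.0 | 0 disables the discriminator |
| deep-supervision weights | 1, ½, ¼, ⅛ | per-stage loss weights |

The `tiny` configurations (16³ volumes, patch 4, D = 32, 2+2 layers) are
the package's desk-scale operating point; the test suite and the
acceptance script run everything at that scale, with the occurrence
statistics exercised at 32–48³ grids and 200–500 simulated cases. The
full-scale defaults above are the recipe the model types describe; nothing
in the package requires running them.

## Numerical and design choices

* **k rounding**: `k = round((1 − ratio)·n)`; exact at the defaults
  (0.25 · 4096 = 1024).
* **Zero-weight patches** (background under the prior) can never become
  visible, stay permanently masked, and *do* count toward the
  reconstruction loss like any other masked token.
* **Center crop**: on an odd size difference the extra voxel is trimmed
  from the high side (low offset = diff // 2).
* **DSC convention**: two empty masks score 1. **HD95**: surfaces are mask
  voxels with a background face-neighbor (array border counts as
  background); distances are pooled symmetrically and the 95th percentile
  taken with linear interpolation; an empty mask returns a configurable
  sentinel (default NaN) because the percentile is undefined.
* **Voxel volume**: the occurrence statistic defaults to voxel volume 1,
  making `V_Ri` the voxel count; physical volumes are an option.
* **Checkpoints**: a single `.npz` archive of named parameter arrays plus a
  JSON config block; encoder extraction filters by parameter-name prefix
  and round-trips bitwise.
* **Per-step resampling**: a fresh visible set is drawn every time an image
  is visited, increasing patch coverage across epochs.
* **Learning rate**: constant; no schedule is applied.

## Known limitations

* Inputs must already be co-registered; the package validates shape/affine
  agreement and never resamples or registers.
* The float64 numpy engine is orders of magnitude slower than a GPU
  framework; full-scale (128³, D = 384) pre-training is out of its intended
  range.
* The windowed-attention mode is a contiguous-chunk simplification, not a
  shifted-window scheme.
* Fixture tumors are spatially unstructured Bernoulli fields; metrics such
  as HD95 on them do not reflect clinical geometry.
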