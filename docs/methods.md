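# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `maefunet`.

## Coverage-weighted masked-autoencoder pretraining

A vision transformer (ViT) encoder is pretrained by masking a fraction
`mask_ratio` of image patches uniformly at random and training a lighter
transformer decoder to reconstruct the masked patches only. For a batch of
N slices the loss is

```
L = (1/N) * Σ_i  w_i * l_i
```

where `l_i` is the mean squared error over the masked patches of sample
`i`, and `w_i ∈ [0, 1]` is a brain-coverage weight. The divisor is N, not
`Σ w_i`: the loss is linear in the weights and reduces to the plain mean
under unit weights. Aggregated brain-MRI cohorts contain many slices with
little or no brain content; weighting by the fraction of pixels inside the
binary brain mask down-weights those slices without discarding them.

Choices the formulation leaves open, and what this package does:

* **Weight function.** `w_i` is the raw brain-pixel fraction with a
  configurable floor (default 0). A linear fraction is the simplest
  monotone choice; it is isolated in `coverage_weight` so alternative
  shapes can be swapped in.
* **Mask ratio** defaults to 0.75, the standard masked-autoencoder value.
* **Masked-count rounding** is round-half-away-from-zero, stated so runs
  are exactly reproducible.
* **Per-patch target normalisation** exists (`norm_pix_targets`) but is off
  by default; the loss as written is plain MSE on masked patches.
* **[CLS] token** participates in the encoder and is excluded from
  reconstruction. Positional embeddings are fixed 2D sine-cosine, chosen
  for determinism. Inputs are single-channel.
* **Decoder sizing** is configurable (`decoder_dim`, `decoder_depth`); the
  full-scale default follows the usual lightweight-decoder sizing (512-d,
  8 layers). The desk-scale preset uses a 2-layer decoder: in small
  experiments a 1-layer decoder measurably degraded the encoder's
  transferable features.

Full-scale configuration is ViT-Base shaped: 224×224 inputs, 16×16
patches, 12 encoder layers, 768-d embeddings. The desk preset
(`ViTConfig.tiny`) uses 64×64 inputs with 4×4 patches so its 16×16 token
grid is close to the 14×14 grid of the full configuration, 32-d
embeddings, and 4 encoder layers.

## Frozen-encoder linear probing

For sequence classification the encoder is frozen and the final-layer,
post-normalisation [CLS] embedding feeds a single affine head
(`C × (d + 1)` trainable parameters; 6,152 for C = 8 on a 768-d encoder).
The loss is multi-class cross-entropy `−z_y + log Σ_j exp z_j`, computed
through a shifted log-sum-exp. Evaluation uses argmax with lowest-index
tie-breaking; per-class accuracy is macro, overall accuracy micro. No
augmentation is applied at probe evaluation time.

## MAE-FUnet

The segmenter runs two streams over the same slice: a U-Net (blocks of two
3×3 convolutions, each with channel LayerNorm and ReLU; 2×2 max-pool
downsampling; nearest-neighbour upsampling; skip connections; channels
doubling from `base_dim`) and the frozen pretrained encoder. Selected
encoder layers (default 1, 3, 6, 9, 12 at full scale) are fused into the
decoder path: the deepest selected layer at the bottleneck, then
successively shallower layers at successively higher-resolution decoder
stages — aligning semantic depth with spatial coarseness. Token maps are
layer-normalised, linearly projected to the CNN channel width, reshaped to
the patch grid and resized to the stage resolution.

Three interchangeable fusion strategies return the CNN feature shape:

* **concat** (default): channel concatenation, then a learned 1×1
  projection back to the CNN width;
* **add**: element-wise sum;
* **attention**: single-head cross-attention (CNN features as queries, MAE
  features as keys/values) residual-added to the CNN stream.

**Gated fusion.** Every strategy passes its transformer contribution
through a learnable scalar gate initialised at zero (for concat, the CNN
half of the projection additionally starts as the identity). A freshly
built fused model therefore behaves exactly like its backbone, and the
global-context pathway opens only as gradient descent finds it useful.
Without the gate, randomly initialised fusion perturbs the CNN stream and
can erase the benefit of pretraining at small step budgets; with it, the
fused model tracks its backbone from the first step and in paired runs
typically matches or exceeds it, with the clearest advantage being
stability (seeds at which the bare backbone diverges leave the fused model
unaffected). On easy tasks where every method nears the ceiling, the
fused-vs-backbone margin is small and can fall within seed-to-seed noise.
The gate is a zero-initialised residual-branch scaling in the layerscale
family and is the package's own design choice; `gated=False` restores
ungated fusion.

Decoder-side fusion (rather than encoder-side) was chosen deliberately;
the frozen encoder means fused features are constant per slice and are
cached during training. **MAE-direct**, the ablation baseline, reshapes
final-layer tokens to the patch grid and upsamples through a small
convolutional head — no skip connections, no multi-level fusion.

## Hybrid segmentation loss

`L_total = λ_dice·L_dice + λ_focal·L_focal + λ_ce·L_ce`, all λ = 1 by
default.

* Soft Dice, per sample, averaged over **all classes including
  background**: per class `1 − (2Σpg + ε)/(Σp² + Σg² + ε)` with
  ε = 1e−5; an absent class contributes `1 − ε/ε = 0`. Batch reduction is
  the mean of per-sample values.
* Focal: mean over pixels of `−α(1−p)^γ log p` on the true-class
  probability, γ = 2, α = 0.25. Probabilities are clipped to [1e−8, 1]
  before the logarithm; the clipping is part of the contract. With γ = 0,
  α = 1 it reduces exactly to pixel cross-entropy.
* Cross-entropy: computed from logits via log-sum-exp.

Argmax label maps resolve ties to the lowest class index.

## Evaluation

Dice = 2|P∩G|/(|P|+|G|), IoU = |P∩G|/|P∪G|, with empty-vs-empty scoring 1
(the same degenerate case the Dice ε guards). Dataset aggregation is
pooled per class over all evaluated slices (micro); per-slice averaging is
a config switch. Mean rows exclude the background class. Sweep dispersion
is the sample (n−1) standard deviation. Trainable-parameter accounting
counts only non-frozen parameters.

## Synthetic phantoms

`phantom_gen` emulates what the restricted cohorts provide: multi-tissue
head geometry with exact masks and labels. A subject is a nest of
ellipsoid shells (skull rim, CSF, cortical gray, white matter) containing
paired elongated ventricles and k small deep gray structures (default 3)
strictly inside white matter — giving the thin-elongated and small-blob
difficulty axes of real anatomical segmentation. Geometry is jittered per
subject by a seeded random affine (±5% scale/rotation/shift). Rendering
maps tissue label → mean intensity through a per-pseudo-sequence contrast
table whose orderings differ between sequences (pseudo-T1: white > gray >
CSF; pseudo-T2: CSF > gray > white; a suppressed-CSF FLAIR analogue; etc.),
multiplied by a smooth order-2 polynomial bias field (mean-normalised to 1,
±15% amplitude) and degraded with additive Gaussian noise (σ = 3 on a
0–97 intensity scale). Spacing defaults to isotropic 1 mm and can be made
anisotropic to exercise voxel-fraction resampling. Whole-volume slicing
yields a substantial fraction of slices with <10% brain coverage, so the
coverage weighting is genuinely exercised.

The phantoms are deliberately *not* anatomically realistic and contain no
pathology or acquisition physics. Passing benchmarks on them demonstrates
that the pipeline's mechanics (pretraining transfer, fusion, losses,
protocol) behave as designed — not that any accuracy number transfers to
clinical data.

## Few-shot protocol at desk scale

The benchmark mirrors the study shape with sizes chosen to run on one CPU:
pretrain the tiny encoder on 500 slices from ~32 phantom subjects (300
steps, batch 16, AdamW), train each segmenter on 10 labelled slices
stride-sampled from 2 held-out subjects (300 steps, batch 8), and evaluate
on 100 slices from 8 further subjects. Subject pools are disjoint and a
train/test overlap is a hard error. All methods share the labelled subset,
seed, initialisation stream, and optimisation budget; MAE-FUnet and
MAE-direct share one frozen encoder. The full-scale recipe (AdamW, 1e−4,
batch 48) is kept as the large-preset default; the desk presets use 1e−3
(pretraining 3e−3) because tiny models on small batches converge
proportionally slower at the full-scale rate.

## Numerical core

No deep-learning framework is used: `maefunet.nn` is a compact reverse-mode
automatic-differentiation engine on numpy float64 arrays (broadcasting
arithmetic, matmul, conv via im2col, max-pool, nearest resize, gather /
scatter, softmax / log-sum-exp) with AdamW. Every primitive's gradient is
tested against central finite differences. Float64 plus single-threaded
BLAS makes runs bit-reproducible under a fixed seed; a global seed fans out
to named substreams (data sampling, masking, initialisation, batching) so
components can be re-seeded independently.

## Known limitations

* Phantom geometry is ellipsoidal; no cortical folding, partial-volume
  mixing, or pathology. Absolute scores on phantoms overstate clinical
  performance by construction.
* The full-scale (ViT-Base, 224) configuration is exercised for shape and
  parameter accounting, not trained here.
* Cross-attention fusion is quadratic in pixel count per stage and is
  intended for coarse stages / small inputs at desk scale.
* Stride sampling uses a zero offset; the sampling offset is configurable
  but not randomised.
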