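# maefunet

Few-shot brain-MRI transformers: coverage-weighted masked-autoencoder
(MAE) pretraining, frozen-encoder linear probing for MRI sequence
identification, and **MAE-FUnet** — a hybrid segmenter that fuses U-Net
features with frozen MAE embeddings — for skull stripping and multi-class
anatomical segmentation under small annotation budgets.

Annotated brain MRI is scarce; the practical question is how much of a
large self-supervised pretraining investment can be recycled into
downstream tasks with ten-odd labelled slices. This package implements
that workflow end-to-end for researchers who want to study it on synthetic
head phantoms (generated internally, with exact masks and labels) or on
their own NIfTI volumes.

## The models

**Pretraining.** A ViT encoder / light decoder reconstructs masked image
patches; the batch loss is the coverage-weighted average of per-sample
masked-patch MSEs,

    L = (1/N) Σᵢ wᵢ·l̃ᵢ ,   wᵢ = max(brain-pixel fraction, floor),

so slices dominated by non-brain content are down-weighted.

**Classification.** The frozen encoder's final [CLS] embedding feeds one
affine layer trained with cross-entropy `−z_y + log Σⱼ e^{z_j}` — only
C·(d+1) trainable parameters (6,152 for 8 classes on a 768-d encoder).

**Segmentation.** MAE-FUnet runs a U-Net backbone and fuses projected
token maps from selected frozen-encoder layers into the bottleneck and
each decoder stage, by concatenation (default), addition, or single-head
cross-attention — all gated so fusion starts as the identity on the CNN
stream. Training uses the hybrid loss

    L = λ_dice·L_dice + λ_focal·L_focal + λ_ce·L_ce   (all λ = 1),

with soft Dice over all classes including background, focal loss
(γ = 2, α = 0.25), and pixel cross-entropy. Evaluation reports per-class
and mean Dice = 2|P∩G|/(|P|+|G|) and IoU = |P∩G|/|P∪G|.

See `docs/methods.md` for assumptions, parameter defaults, and design
rationale. There is no deep-learning framework dependency: models run on
the package's own gradient-checked numpy autodiff core (`maefunet.nn`).

## Worked example

Run the paired few-shot skull-stripping benchmark on phantoms — pretrain a
tiny encoder on 500 unlabelled slices (300 steps), train MAE-FUnet, a
backbone-only U-Net, and the MAE-direct head on the *same* 10 labelled
slices, and evaluate all three on 100 held-out slices:

```python
from maefunet.experiments import fewshot_skullstrip_benchmark

res = fewshot_skullstrip_benchmark(seed=1)
for method, report in res["reports"].items():
    print(f"{method:>12}  IoU {100*report.mean_iou:5.2f}  Dice {100*report.mean_dice:5.2f}")
```

```
   mae_funet  IoU 87.45  Dice 93.30
        unet  IoU 87.00  Dice 93.05
  mae_direct  IoU 83.97  Dice 91.29
```

The fused model attains the highest Dice/IoU of the three under an
identical budget; the direct head (no multi-level fusion) trails. Because
the phantom task is easy, converged scores sit close together and the
FUnet-vs-U-Net margin varies with the seed — the clearest effect is
stability: at some seeds the un-pretrained U-Net destabilises entirely
(Dice ≈ 0.69) while MAE-FUnet stays put, the few-shot robustness the
architecture is built for.
Phantom scores say nothing about clinical accuracy (see the limitations
section of the methods note); they validate the pipeline's mechanics.

A command-line surface wraps the same library:

```sh
maefunet phantom-gen --out-dir out/phantoms --n-subjects 2 --seed 3
maefunet pretrain    --out-dir out/pretrain --seed 1
maefunet probe-train --encoder out/pretrain/encoder.npz --out-dir out/probe
maefunet probe-eval  --encoder out/pretrain/encoder.npz --probe out/probe/probe.npz --out-dir out/eval
maefunet seg-eval    --out-dir out/seg --seed 1
```

Every command writes a `manifest.json` (resolved config, seed, package
version, input digests) sufficient to reproduce the run.

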