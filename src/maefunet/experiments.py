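"""Few-shot experiment protocols on phantom data.

Reproduces the shape of the study design at desk scale: self-supervised
pretraining on unlabelled slices, then paired few-shot segmentation runs —
MAE-FUnet vs the identical backbone-only U-Net vs the MAE-direct head —
trained on the same sampled subset with the same seed and budget, and
evaluated on a fixed held-out subject pool. Train and test subject pools
are disjoint by construction and guarded by a hard error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .funet import (
    FUnetConfig,
    HybridLossConfig,
    MAEDirect,
    MAEFUnet,
    UNet,
    train_segmenter,
)
from .mae import MAEModel, ViTConfig, model_from_checkpoint, pretrain
from .metrics import MetricReport, evaluate_dataset
from .phantom import PhantomSpec, brain_mask_from_labels, make_phantom_volume, render_sequence
from .seeding import substream
from .volume_io import PreprocessConfig, SliceSample, StridePlan, Volume, extract_slices

__all__ = [
    "FewshotConfig",
    "build_slice_bank",
    "fewshot_skullstrip_benchmark",
    "sample_size_sweep",
]

_SEQ_CYCLE = ("pseudo_t1", "pseudo_t2", "pseudo_flair", "pseudo_pd")


@dataclass
class FewshotConfig:
    """Desk-scale few-shot skull-stripping protocol."""

    image_size: int = 64
    n_pretrain_slices: int = 500
    pretrain_steps: int = 300
    pretrain_batch: int = 16
    pretrain_lr: float = 3e-3
    n_train_slices: int = 10
    n_test_slices: int = 100
    seg_steps: int = 300
    seg_batch: int = 8
    learning_rate: float = 1e-3
    fusion_strategy: str = "concat"
    methods: tuple[str, ...] = ("mae_funet", "unet", "mae_direct")


def build_slice_bank(
    subject_seeds,
    spec: PhantomSpec,
    image_size: int,
    stride: int = 4,
    max_slices: int | None = None,
) -> list[SliceSample]:
    """Stride-sampled axial slices (image + brain mask + binary labels)
    across a pool of phantom subjects, sequences cycling per subject."""
    cfg = PreprocessConfig(target_size=(image_size, image_size))
    plan = StridePlan(stride=stride, axes=(2,))
    bank: list[SliceSample] = []
    for i, sub in enumerate(subject_seeds):
        labels, mask, spacing = make_phantom_volume(spec, sub)
        seq = _SEQ_CYCLE[i % len(_SEQ_CYCLE)]
        intens = render_sequence(labels, seq, spec, noise_seed=sub)
        vol = Volume(intens, spacing, f"phantom-{sub}")
        mvol = Volume(mask, spacing)
        bank.extend(
            extract_slices(
                vol, plan, cfg, mask_volume=mvol, label_volume=mvol,
                volume_id=f"phantom-{sub}",
            )
        )
        if max_slices is not None and len(bank) >= max_slices:
            return bank[:max_slices]
    return bank


def _check_disjoint(train_subjects, test_subjects) -> None:
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise ValueError(f"train/test subject leakage: {sorted(overlap)}")


def fewshot_skullstrip_benchmark(
    seed: int, cfg: FewshotConfig | None = None, encoder_ckpt: dict | None = None
) -> dict:
    """Paired few-shot skull stripping: returns per-method MetricReports.

    All methods see the identical labelled subset, seed, and optimisation
    budget; MAE-FUnet and MAE-direct share one pretrained frozen encoder.
    """
    cfg = cfg if cfg is not None else FewshotConfig()
    spec = PhantomSpec(grid_size=max(64, cfg.image_size))
    rng = substream(seed, "fewshot-subjects")
    # disjoint subject pools: pretraining, supervised training, held-out test
    n_pre_subj = -(-cfg.n_pretrain_slices // (spec.grid_size // 4))
    all_subjects = rng.choice(2**31 - 1, size=n_pre_subj + 2 + 8, replace=False)
    pre_subjects = all_subjects[:n_pre_subj]
    train_subjects = all_subjects[n_pre_subj : n_pre_subj + 2]
    test_subjects = all_subjects[n_pre_subj + 2 :]
    _check_disjoint(train_subjects, test_subjects)
    _check_disjoint(pre_subjects, test_subjects)

    if encoder_ckpt is None:
        pre_bank = build_slice_bank(
            pre_subjects, spec, cfg.image_size, stride=4,
            max_slices=cfg.n_pretrain_slices,
        )
        encoder_ckpt = pretrain(
            pre_bank,
            ViTConfig.tiny(cfg.image_size),
            seed=seed,
            steps=cfg.pretrain_steps,
            batch_size=cfg.pretrain_batch,
            learning_rate=cfg.pretrain_lr,
        )
    encoder = model_from_checkpoint(encoder_ckpt)
    encoder.freeze()

    train_bank = build_slice_bank(train_subjects, spec, cfg.image_size, stride=5)
    pick = substream(seed, "fewshot-train-pick")
    train_idx = pick.choice(len(train_bank), size=cfg.n_train_slices, replace=False)
    train_set = [train_bank[i] for i in sorted(train_idx)]
    test_set = build_slice_bank(
        test_subjects, spec, cfg.image_size, stride=4, max_slices=cfg.n_test_slices
    )

    fcfg = FUnetConfig.tiny(
        num_classes=2, image_size=cfg.image_size, fusion_strategy=cfg.fusion_strategy
    )
    models = {}
    for method in cfg.methods:
        if method == "mae_funet":
            models[method] = MAEFUnet(fcfg, encoder, init_seed=seed)
        elif method == "unet":
            models[method] = UNet(fcfg, init_seed=seed)
        elif method == "mae_direct":
            models[method] = MAEDirect(encoder, 2, init_seed=seed)
        else:
            raise ValueError(f"unknown method {method!r}")

    results: dict = {"reports": {}, "encoder_digest": encoder.weight_digest()}
    truth = [s.label_grid.astype(int) for s in test_set]
    for method, model in models.items():
        train_segmenter(
            train_set,
            model,
            HybridLossConfig(),
            seed=seed,
            steps=cfg.seg_steps,
            batch_size=cfg.seg_batch,
            learning_rate=cfg.learning_rate,
        )
        preds = []
        for j in range(0, len(test_set), 16):
            imgs = np.stack([s.image for s in test_set[j : j + 16]])
            preds.extend(model(imgs).label_map)
        results["reports"][method] = evaluate_dataset(preds, truth, classes=[0, 1])
    results["encoder_digest_after"] = encoder.weight_digest()
    results["encoder_ckpt"] = encoder_ckpt
    results["n_train"] = len(train_set)
    results["n_test"] = len(test_set)
    return results


def sample_size_sweep(
    seed: int | tuple[int, ...],
    sample_sizes,
    cfg: FewshotConfig | None = None,
    benchmark=fewshot_skullstrip_benchmark,
) -> dict:
    """Run the paired benchmark over labelled-set sizes (and optionally
    several seeds), reusing one pretrained encoder per seed.

    Returns method -> list of (iou, dice), one entry per (seed, size) grid
    point in order.
    """
    from dataclasses import replace

    cfg = cfg if cfg is not None else FewshotConfig()
    seeds = (seed,) if isinstance(seed, int) else tuple(seed)
    if not seeds:
        raise ValueError("need at least one seed")
    grid: dict = {m: [] for m in cfg.methods}
    for s in seeds:
        encoder_ckpt = None
        for n in sample_sizes:
            run_cfg = replace(cfg, n_train_slices=int(n))
            res = benchmark(s, run_cfg, encoder_ckpt=encoder_ckpt)
            encoder_ckpt = res.get("encoder_ckpt")
            for m in cfg.methods:
                rep = res["reports"][m]
                grid[m].append((rep.mean_iou, rep.mean_dice))
    return grid
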