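"""Masked-autoencoder vision transformer with coverage-weighted pretraining.

The encoder is a standard ViT (16x16 patches, 12 layers at full scale); the
decoder is a lighter transformer that reconstructs only the masked patches.
The batch loss is the weighted average of per-sample masked-patch MSEs,

    L = (1/N) * sum_i  w_i * l_i ,

where w_i is the fraction of slice pixels inside the brain mask (optionally
floored), so slices dominated by non-brain content or cropped fields of view
are down-weighted. Note the divisor is N, not sum(w): the loss is linear in
the weights and reduces to the plain mean under unit weights.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .seeding import substream

__all__ = [
    "CHECKPOINT_FORMAT",
    "EncoderOutput",
    "MAEModel",
    "MaskingPlan",
    "ViTConfig",
    "coverage_weight",
    "load_checkpoint",
    "patchify",
    "per_sample_masked_mse",
    "pretrain",
    "sample_masking",
    "save_checkpoint",
    "sincos_pos_embed_2d",
    "unpatchify",
    "weighted_batch_loss",
]

CHECKPOINT_FORMAT = "maefunet-checkpoint-v1"


@dataclass(frozen=True)
class ViTConfig:
    image_size: int = 224
    patch_size: int = 16
    channels: int = 1
    encoder_dim: int = 768
    encoder_depth: int = 12
    encoder_heads: int = 12
    decoder_dim: int = 512
    decoder_depth: int = 8
    decoder_heads: int = 16
    mlp_ratio: float = 4.0
    mask_ratio: float = 0.75
    norm_pix_targets: bool = False

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if not (0 < self.mask_ratio < 1):
            raise ValueError("mask_ratio must be in (0, 1)")
        if self.encoder_depth < 1 or self.decoder_depth < 1:
            raise ValueError("encoder/decoder depth must be >= 1")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_tokens(self) -> int:
        return self.grid_size**2

    @classmethod
    def tiny(cls, image_size: int = 64) -> "ViTConfig":
        """Desk-scale preset for tests and phantom experiments.

        patch 4 on 64-pixel slices gives a 16x16 token grid, close to the
        14x14 grid of the full-scale configuration (16 on 224).
        """
        return cls(
            image_size=image_size,
            patch_size=4,
            encoder_dim=32,
            encoder_depth=4,
            encoder_heads=4,
            decoder_dim=32,
            decoder_depth=2,
            decoder_heads=4,
            mlp_ratio=2.0,
        )


@dataclass(frozen=True)
class MaskingPlan:
    """Which token indices are masked, for one sample."""

    masked_indices: np.ndarray
    n_tokens: int
    ratio: float
    seed: int

    @property
    def visible_indices(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_tokens), self.masked_indices)

    @property
    def n_masked(self) -> int:
        return len(self.masked_indices)


@dataclass
class EncoderOutput:
    """Per-layer patch-token embeddings plus the final [CLS] embedding."""

    per_layer_tokens: list  # E tensors of shape (B, n_visible_or_all, dim)
    cls_embedding: Tensor  # (B, dim), after the final normalisation
    tokens_final: Tensor  # (B, n, dim), after the final normalisation


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, H, W) -> (B, N, p*p) in row-major raster order of the patch grid."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    b, h, w = images.shape
    if h % patch_size or w % patch_size:
        raise ValueError(f"image size {(h, w)} not divisible by patch {patch_size}")
    gh, gw = h // patch_size, w // patch_size
    x = images.reshape(b, gh, patch_size, gw, patch_size)
    return x.transpose(0, 1, 3, 2, 4).reshape(b, gh * gw, patch_size * patch_size)


def unpatchify(patches: np.ndarray, patch_size: int, image_size: int) -> np.ndarray:
    patches = np.asarray(patches)
    b, n, pp = patches.shape
    g = image_size // patch_size
    if n != g * g or pp != patch_size * patch_size:
        raise ValueError("patch matrix inconsistent with image/patch size")
    x = patches.reshape(b, g, g, patch_size, patch_size)
    return x.transpose(0, 1, 3, 2, 4).reshape(b, image_size, image_size)


def sample_masking(n_tokens: int, ratio: float, seed: int) -> MaskingPlan:
    """Uniform masking without replacement; deterministic per seed."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    m = _round_half_away(ratio * n_tokens)
    if m == 0 or m == n_tokens:
        raise ValueError(f"degenerate masking plan: {m} of {n_tokens} masked")
    rng = substream(seed, "masking")
    idx = np.sort(rng.permutation(n_tokens)[:m])
    return MaskingPlan(masked_indices=idx, n_tokens=n_tokens, ratio=ratio, seed=seed)


def sincos_pos_embed_2d(grid: int, dim: int) -> np.ndarray:
    """Fixed 2D sine-cosine positional embedding, (grid*grid, dim)."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4 for 2D sin-cos")
    d4 = dim // 4
    omega = 1.0 / (10000 ** (np.arange(d4) / d4))
    pos = np.arange(grid)
    out = pos[:, None] * omega[None, :]
    emb1 = np.concatenate([np.sin(out), np.cos(out)], axis=1)  # (grid, dim/2)
    row = np.repeat(emb1, grid, axis=0)
    col = np.tile(emb1, (grid, 1))
    return np.concatenate([row, col], axis=1)


class MAEModel(nn.Module):
    """ViT encoder + lightweight transformer decoder."""

    def __init__(self, cfg: ViTConfig, init_seed: int = 0):
        object.__setattr__(self, "cfg", cfg)
        rng = substream(init_seed, "mae-init")
        p2 = cfg.patch_size**2 * cfg.channels
        self.patch_embed = nn.Linear(p2, cfg.encoder_dim, rng)
        self.cls_token = Tensor(
            rng.standard_normal((1, 1, cfg.encoder_dim)) * 0.02, requires_grad=True
        )
        object.__setattr__(
            self, "pos_embed", sincos_pos_embed_2d(cfg.grid_size, cfg.encoder_dim)
        )
        self.blocks = [
            nn.TransformerBlock(cfg.encoder_dim, cfg.encoder_heads, cfg.mlp_ratio, rng)
            for _ in range(cfg.encoder_depth)
        ]
        self.norm = nn.LayerNorm(cfg.encoder_dim)
        self.decoder_embed = nn.Linear(cfg.encoder_dim, cfg.decoder_dim, rng)
        self.mask_token = Tensor(
            rng.standard_normal((1, 1, cfg.decoder_dim)) * 0.02, requires_grad=True
        )
        object.__setattr__(
            self, "dec_pos_embed", sincos_pos_embed_2d(cfg.grid_size, cfg.decoder_dim)
        )
        self.decoder_blocks = [
            nn.TransformerBlock(cfg.decoder_dim, cfg.decoder_heads, cfg.mlp_ratio, rng)
            for _ in range(cfg.decoder_depth)
        ]
        self.decoder_norm = nn.LayerNorm(cfg.decoder_dim)
        self.decoder_pred = nn.Linear(cfg.decoder_dim, p2, rng)

    # -- encoder -----------------------------------------------------------
    def encode(
        self, images: np.ndarray, visible_idx: np.ndarray | None = None
    ) -> EncoderOutput:
        """Forward the encoder.

        ``visible_idx`` (B, K) restricts the sequence to visible tokens
        (pretraining); without it every token passes (inference / fusion).
        Per-layer patch-token outputs are exposed for decoder-side fusion;
        the [CLS] embedding is taken after the final normalisation.
        """
        cfg = self.cfg
        patches = patchify(images, cfg.patch_size)
        if patches.shape[1] != cfg.n_tokens:
            raise ValueError(
                f"image yields {patches.shape[1]} tokens, config expects {cfg.n_tokens}"
            )
        tokens = self.patch_embed(Tensor(patches)) + Tensor(self.pos_embed[None])
        if visible_idx is not None:
            tokens = nn.gather_tokens(tokens, visible_idx)
        b = tokens.shape[0]
        cls = self.cls_token * Tensor(np.ones((b, 1, 1)))
        x = nn.concat([cls, tokens], axis=1)
        per_layer = []
        for blk in self.blocks:
            x = blk(x)
            per_layer.append(x[:, 1:, :])
        x = self.norm(x)
        return EncoderOutput(
            per_layer_tokens=per_layer,
            cls_embedding=x[:, 0, :],
            tokens_final=x[:, 1:, :],
        )


    # -- decoder -----------------------------------------------------------
    def decode_reconstruct(
        self, enc: EncoderOutput, visible_idx: np.ndarray
    ) -> Tensor:
        """Predict every patch; only masked positions will enter the loss."""
        cfg = self.cfg
        if enc.tokens_final.shape[1] != visible_idx.shape[1]:
            raise ValueError("encoder output does not match the masking plan")
        x = self.decoder_embed(enc.tokens_final)
        full = nn.scatter_tokens(x, visible_idx, cfg.n_tokens)
        b = full.shape[0]
        batch = np.arange(b)[:, None]
        vis_mask = np.zeros((b, cfg.n_tokens, 1))
        vis_mask[batch, visible_idx] = 1.0
        full = full + self.mask_token * Tensor(1.0 - vis_mask)
        full = full + Tensor(self.dec_pos_embed[None])
        for blk in self.decoder_blocks:
            full = blk(full)
        return self.decoder_pred(self.decoder_norm(full))


def per_sample_masked_mse(
    pred: Tensor,
    target_patches: np.ndarray,
    masked_idx: np.ndarray,
    norm_pix_targets: bool = False,
) -> Tensor:
    """Mean squared error over masked patches only, per sample -> (B,)."""
    target = np.asarray(target_patches, dtype=np.float64)
    if norm_pix_targets:
        mu = target.mean(axis=-1, keepdims=True)
        sd = target.std(axis=-1, keepdims=True)
        target = (target - mu) / (sd + 1e-6)
    pred_m = nn.gather_tokens(pred, masked_idx)
    batch = np.arange(target.shape[0])[:, None]
    target_m = target[batch, masked_idx]
    diff = pred_m - Tensor(target_m)
    return (diff * diff).mean(axis=2).mean(axis=1)


def coverage_weight(brain_mask: np.ndarray, floor: float = 0.0) -> float:
    """w = max(fraction of pixels inside the brain mask, floor)."""
    m = np.asarray(brain_mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("brain mask must be binary (values 0/1)")
    return float(max(m.mean(), floor))


def weighted_batch_loss(per_sample_loss: Tensor, weights: np.ndarray) -> Tensor:
    """L = (1/N) sum_i w_i * l_i  (divisor is N, not the weight sum)."""
    w = np.asarray(weights, dtype=np.float64)
    n = per_sample_loss.shape[0]
    if w.shape != (n,):
        raise ValueError("one weight per sample required")
    return (per_sample_loss * Tensor(w)).sum() * (1.0 / n)


def _batch_masking(
    n_tokens: int, ratio: float, batch_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample uniform masking with a common count -> (masked, visible)."""
    m = _round_half_away(ratio * n_tokens)
    masked = np.stack([np.sort(rng.permutation(n_tokens)[:m]) for _ in range(batch_size)])
    visible = np.stack(
        [np.setdiff1d(np.arange(n_tokens), row) for row in masked]
    )
    return masked, visible


def forward_pretrain_loss(
    model: MAEModel,
    images: np.ndarray,
    brain_masks: list[np.ndarray] | None,
    rng: np.random.Generator,
    weight_floor: float = 0.0,
) -> Tensor:
    """One coverage-weighted reconstruction loss on a batch."""
    cfg = model.cfg
    masked, visible = _batch_masking(cfg.n_tokens, cfg.mask_ratio, len(images), rng)
    enc = model.encode(images, visible_idx=visible)
    pred = model.decode_reconstruct(enc, visible)
    target = patchify(images, cfg.patch_size)
    losses = per_sample_masked_mse(pred, target, masked, cfg.norm_pix_targets)
    if brain_masks is None:
        weights = np.ones(len(images))
    else:
        weights = np.array([coverage_weight(m, weight_floor) for m in brain_masks])
    return weighted_batch_loss(losses, weights)


def pretrain(
    slice_source,
    cfg: ViTConfig,
    seed: int = 0,
    steps: int = 300,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
    weight_decay: float = 0.01,
    weight_floor: float = 0.0,
    log_path=None,
) -> dict:
    """Pretrain an MAE on (image, brain_mask) pairs; returns a checkpoint.

    ``slice_source`` is a sequence of SliceSample or (image, mask) tuples.
    Deterministic given the seed and the data order.
    """
    pairs = []
    for item in slice_source:
        if hasattr(item, "image"):
            pairs.append((item.image, item.brain_mask))
        else:
            pairs.append((item[0], item[1]))
    if not pairs:
        raise ValueError("empty slice source")
    model = MAEModel(cfg, init_seed=seed)
    opt = nn.AdamW(model.parameters(), lr=learning_rate, weight_decay=weight_decay)
    batch_rng = substream(seed, "pretrain-batches")
    mask_rng = substream(seed, "pretrain-masking")
    log_lines = []
    import time as _time

    for step in range(steps):
        idx = batch_rng.integers(0, len(pairs), size=min(batch_size, len(pairs)))
        images = np.stack([pairs[i][0] for i in idx])
        masks = [pairs[i][1] for i in idx]
        if any(m is None for m in masks):
            masks = None
        loss = forward_pretrain_loss(model, images, masks, mask_rng, weight_floor)
        opt.zero_grad()
        loss.backward()
        opt.step()
        log_lines.append(f"{step}\t{float(loss.data):.6f}\t{_time.time():.3f}")
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write("\n".join(log_lines) + ("\n" if log_lines else ""))
    return {
        "format_version": CHECKPOINT_FORMAT,
        "kind": "mae",
        "config": asdict(cfg),
        "seed": seed,
        "state": model.state_dict(),
        "optimizer": opt.state_dict(),
    }


def save_checkpoint(ckpt: dict, path) -> None:
    meta = {k: ckpt[k] for k in ("format_version", "kind", "config", "seed")}
    arrays = {f"state/{k}": v for k, v in ckpt["state"].items()}
    opt = ckpt.get("optimizer")
    if opt is not None:
        arrays["opt/t"] = np.array(opt["t"])
        for i, m in enumerate(opt["m"]):
            arrays[f"opt/m{i}"] = m
        for i, v in enumerate(opt["v"]):
            arrays[f"opt/v{i}"] = v
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {
            k[len("state/") :]: data[k] for k in data.files if k.startswith("state/")
        }
        opt = None
        if "opt/t" in data.files:
            n = sum(1 for k in data.files if k.startswith("opt/m"))
            opt = {
                "t": int(data["opt/t"]),
                "m": [data[f"opt/m{i}"] for i in range(n)],
                "v": [data[f"opt/v{i}"] for i in range(n)],
            }
    meta["state"] = state
    meta["optimizer"] = opt
    return meta


def model_from_checkpoint(ckpt: dict) -> MAEModel:
    cfg = ViTConfig(**ckpt["config"])
    model = MAEModel(cfg, init_seed=ckpt.get("seed", 0))
    model.load_state_dict(ckpt["state"])
    return model
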