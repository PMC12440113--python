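"""MAE-FUnet: a U-Net backbone fused with frozen MAE embeddings, plus the
MAE-direct baseline and the hybrid Dice-Focal-cross-entropy loss.

Fusion happens on the decoder path: projected token maps from selected
encoder layers are combined with the CNN feature map at the bottleneck and
at every decoder stage — the deepest selected transformer layer pairs with
the bottleneck (semantic depth aligned), the shallowest with the
highest-resolution stage. Three interchangeable strategies exist:

* ``concat`` — channel concatenation followed by a learned 1x1 projection
  back to the CNN width (the default; strongest in practice),
* ``add`` — element-wise sum,
* ``attention`` — single-head cross-attention with CNN features as queries
  and MAE features as keys/values, residual-added to the CNN features.

All strategies return the CNN feature shape, so the rest of the decoder is
strategy-agnostic. The pretrained encoder is always frozen here.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .mae import MAEModel, ViTConfig
from .nn import Tensor
from .seeding import substream

__all__ = [
    "FUnetConfig",
    "FusionBlock",
    "HybridLossConfig",
    "MAEDirect",
    "MAEFUnet",
    "SegPrediction",
    "TokenProjector",
    "UNet",
    "ce_pixel_loss",
    "dice_loss",
    "focal_loss",
    "fuse",
    "hybrid_loss",
    "train_segmenter",
]

FUSION_STRATEGIES = ("concat", "add", "attention")


@dataclass(frozen=True)
class FUnetConfig:
    num_classes: int
    depth: int = 4
    base_dim: int = 64
    fusion_strategy: str = "concat"
    fusion_layers: tuple[int, ...] = (1, 3, 6, 9, 12)
    image_size: int = 224

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.base_dim <= 0:
            raise ValueError("base_dim must be positive")
        if self.fusion_strategy not in FUSION_STRATEGIES:
            raise ValueError(
                f"unknown fusion strategy {self.fusion_strategy!r}; "
                f"choose from {FUSION_STRATEGIES}"
            )
        if len(self.fusion_layers) != self.depth + 1:
            raise ValueError(
                f"need depth+1={self.depth + 1} fusion layers, got {self.fusion_layers}"
            )
        if self.image_size % (2**self.depth):
            raise ValueError("image_size must be divisible by 2^depth")

    @classmethod
    def tiny(cls, num_classes: int = 2, **kw) -> "FUnetConfig":
        """Desk-scale preset matched to ``ViTConfig.tiny``."""
        kw.setdefault("depth", 2)
        kw.setdefault("base_dim", 8)
        kw.setdefault("fusion_layers", (1, 2, 4))
        kw.setdefault("image_size", 64)
        return cls(num_classes=num_classes, **kw)


@dataclass(frozen=True)
class HybridLossConfig:
    lambda_dice: float = 1.0
    lambda_focal: float = 1.0
    lambda_ce: float = 1.0
    gamma: float = 2.0
    alpha: float = 0.25
    eps: float = 1e-5

    def __post_init__(self):
        if min(self.lambda_dice, self.lambda_focal, self.lambda_ce) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.gamma < 0 or not (0 < self.alpha <= 1) or self.eps <= 0:
            raise ValueError("invalid focal/smoothing parameters")


@dataclass
class SegPrediction:
    logits: Tensor  # (B, C, H, W)

    @property
    def probabilities(self) -> np.ndarray:
        z = self.logits.data
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    @property
    def label_map(self) -> np.ndarray:
        # np.argmax resolves ties to the lowest class index
        return self.logits.data.argmax(axis=1)


class FusionBlock(nn.Module):
    """Combine a CNN feature map with a projected MAE feature map.

    Fusion is gated: the transformer contribution enters through a learned
    scalar gate initialised at zero, so a freshly built fused model behaves
    exactly like its backbone and the global-context pathway is opened by
    gradient descent only where it helps (a zero-init residual-branch
    scaling, in the layerscale family). ``gated=False`` disables this and
    fuses at full strength from the start.
    """

    def __init__(
        self,
        strategy: str,
        channels: int,
        rng: np.random.Generator,
        gated: bool = True,
    ):
        if strategy not in FUSION_STRATEGIES:
            raise ValueError(f"unknown fusion strategy {strategy!r}")
        object.__setattr__(self, "strategy", strategy)
        object.__setattr__(self, "gated", gated)
        if gated:
            self.gate = Tensor(np.zeros(1), requires_grad=True)
        if strategy == "concat":
            self.proj = nn.Conv2d(2 * channels, channels, 1, rng, pad=0)
            if gated:
                # CNN half starts as the identity so the gate alone controls
                # how much projected-MAE signal is mixed in
                w = self.proj.weight.data
                w[:, :channels, 0, 0] = np.eye(channels)
                self.proj.weight.data = w
        elif strategy == "attention":
            self.attn = nn.MultiHeadAttention(channels, 1, rng)

    def _gate(self, x: Tensor) -> Tensor:
        return x * self.gate if self.gated else x

    def __call__(self, cnn_feat: Tensor, mae_feat: Tensor) -> Tensor:
        if cnn_feat.shape != mae_feat.shape:
            raise ValueError(
                f"fusion inputs must be shape-aligned: {cnn_feat.shape} vs {mae_feat.shape}"
            )
        if self.strategy == "add":
            return cnn_feat + self._gate(mae_feat)
        if self.strategy == "concat":
            if not self.gated:
                return self.proj(nn.concat([cnn_feat, mae_feat], axis=1))
            return self.proj(nn.concat([cnn_feat, self._gate(mae_feat)], axis=1))
        b, c, h, w = cnn_feat.shape
        q = cnn_feat.reshape(b, c, h * w).transpose(0, 2, 1)
        kv = mae_feat.reshape(b, c, h * w).transpose(0, 2, 1)
        out = self.attn(q, kv).transpose(0, 2, 1).reshape(b, c, h, w)
        return cnn_feat + self._gate(out)


def fuse(cnn_feat: Tensor, mae_feat: Tensor, block: FusionBlock) -> Tensor:
    """Apply one fusion block; see :class:`FusionBlock` for the strategies."""
    return block(cnn_feat, mae_feat)


class TokenProjector(nn.Module):
    """Reshape per-layer tokens to the patch grid, project channels, resize.

    Tokens are layer-normalised before projection so the fused contribution
    has a controlled scale regardless of which encoder layer it comes from.
    """

    def __init__(self, token_dim: int, target_channels: int, rng):
        self.norm = nn.LayerNorm(token_dim)
        self.proj = nn.Linear(token_dim, target_channels, rng)

    def __call__(self, tokens: Tensor, grid: int, out_h: int, out_w: int) -> Tensor:
        b, n, _ = tokens.shape
        if n != grid * grid:
            raise ValueError(f"{n} tokens do not form a {grid}x{grid} grid")
        x = self.proj(self.norm(tokens))  # (B, N, C)
        x = x.reshape(b, grid, grid, x.shape[-1]).transpose(0, 3, 1, 2)
        return nn.resize_nearest(x, out_h, out_w)


class UNet(nn.Module):
    """Plain U-Net: the CNN backbone of MAE-FUnet, usable standalone.

    Encoder levels halve resolution and double channels from ``base_dim``;
    skip connections feed each decoder stage; a 1x1 head emits logits.
    """

    def __init__(self, cfg: FUnetConfig, init_seed: int = 0, channels_in: int = 1):
        object.__setattr__(self, "cfg", cfg)
        rng = substream(init_seed, "unet-init")
        dims = [cfg.base_dim * (2**i) for i in range(cfg.depth + 1)]
        object.__setattr__(self, "dims", dims)
        self.enc_blocks = [nn.ConvBlock(channels_in, dims[0], rng)] + [
            nn.ConvBlock(dims[i], dims[i + 1], rng) for i in range(cfg.depth - 1)
        ]
        self.bottleneck = nn.ConvBlock(dims[cfg.depth - 1], dims[cfg.depth], rng)
        self.up_convs = [
            nn.Conv2d(dims[i + 1], dims[i], 3, rng) for i in reversed(range(cfg.depth))
        ]
        self.dec_blocks = [
            nn.ConvBlock(2 * dims[i], dims[i], rng) for i in reversed(range(cfg.depth))
        ]
        self.head = nn.Conv2d(dims[0], cfg.num_classes, 1, rng, pad=0)

    # -- backbone pieces, exposed so the fused variant can interleave ------
    def encode_cnn(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        if x.shape[-1] % (2**self.cfg.depth):
            raise ValueError("input size not divisible through the U-Net depth")
        skips = []
        for blk in self.enc_blocks:
            x = blk(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        return skips, self.bottleneck(x)

    def decode_cnn(
        self, skips: list[Tensor], x: Tensor, stage_hook=None
    ) -> Tensor:
        for i, (up, blk) in enumerate(zip(self.up_convs, self.dec_blocks)):
            x = up(nn.upsample2x2(x))
            x = blk(nn.concat([skips[-(i + 1)], x], axis=1))
            if stage_hook is not None:
                x = stage_hook(i, x)
        return self.head(x)

    def __call__(self, images: np.ndarray) -> SegPrediction:
        x = Tensor(np.asarray(images, dtype=np.float64)[:, None])
        skips, bottom = self.encode_cnn(x)
        return SegPrediction(logits=self.decode_cnn(skips, bottom))


class MAEFUnet(nn.Module):
    """U-Net backbone + frozen MAE embeddings fused on the decoder path."""

    def __init__(self, cfg: FUnetConfig, encoder: MAEModel, init_seed: int = 0):
        object.__setattr__(self, "cfg", cfg)
        if max(cfg.fusion_layers) > encoder.cfg.encoder_depth:
            raise ValueError(
                f"fusion layer {max(cfg.fusion_layers)} exceeds encoder depth "
                f"{encoder.cfg.encoder_depth}"
            )
        if encoder.cfg.image_size != cfg.image_size:
            raise ValueError("encoder and segmenter image sizes differ")
        self.encoder = encoder
        self.encoder.freeze()
        self.backbone = UNet(cfg, init_seed=init_seed)
        rng = substream(init_seed, "fusion-init")
        dims = self.backbone.dims
        # deepest selected layer fuses at the bottleneck, then downwards
        # through successively higher-resolution decoder stages
        order = sorted(cfg.fusion_layers, reverse=True)
        object.__setattr__(self, "fusion_order", order)
        fusion_dims = [dims[cfg.depth]] + [dims[i] for i in reversed(range(cfg.depth))]
        self.projectors = [
            TokenProjector(encoder.cfg.encoder_dim, d, rng) for d in fusion_dims
        ]
        self.fusions = [
            FusionBlock(cfg.fusion_strategy, d, rng) for d in fusion_dims
        ]

    def encode_tokens(self, images: np.ndarray) -> list[np.ndarray]:
        """Frozen-encoder token maps for the fusion layers (cacheable)."""
        enc_out = self.encoder.encode(np.asarray(images, dtype=np.float64))
        return [
            enc_out.per_layer_tokens[layer - 1].data.copy()
            for layer in self.fusion_order
        ]

    def __call__(
        self, images: np.ndarray, cached_tokens: list[np.ndarray] | None = None
    ) -> SegPrediction:
        images = np.asarray(images, dtype=np.float64)
        raw = cached_tokens if cached_tokens is not None else self.encode_tokens(images)
        layer_tokens = [Tensor(t) for t in raw]
        grid = self.encoder.cfg.grid_size
        x = Tensor(images[:, None])
        skips, bottom = self.backbone.encode_cnn(x)
        res = self.cfg.image_size // (2**self.cfg.depth)
        mae_feat = self.projectors[0](layer_tokens[0], grid, res, res)
        bottom = self.fusions[0](bottom, mae_feat)

        def stage_hook(i: int, feat: Tensor) -> Tensor:
            r = feat.shape[-1]
            mf = self.projectors[i + 1](layer_tokens[i + 1], grid, r, r)
            return self.fusions[i + 1](feat, mf)

        return SegPrediction(logits=self.backbone.decode_cnn(skips, bottom, stage_hook))


class MAEDirect(nn.Module):
    """Baseline: frozen encoder + a multi-layer CNN segmentation head.

    Final-layer tokens are reshaped to the patch grid and upsampled through
    convolutional stages back to full resolution.
    """

    def __init__(self, encoder: MAEModel, num_classes: int, init_seed: int = 0):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        self.encoder = encoder
        self.encoder.freeze()
        object.__setattr__(self, "num_classes", num_classes)
        rng = substream(init_seed, "maedirect-init")
        n_up = int(np.log2(encoder.cfg.patch_size))
        if 2**n_up != encoder.cfg.patch_size:
            raise ValueError("patch size must be a power of two for the direct head")
        dims = [max(8, 64 // (2**i)) for i in range(n_up + 1)]
        self.in_conv = nn.Conv2d(encoder.cfg.encoder_dim, dims[0], 3, rng)
        self.up_convs = [nn.Conv2d(dims[i], dims[i + 1], 3, rng) for i in range(n_up)]
        self.head = nn.Conv2d(dims[-1], num_classes, 1, rng, pad=0)

    def encode_tokens(self, images: np.ndarray) -> list[np.ndarray]:
        enc_out = self.encoder.encode(np.asarray(images, dtype=np.float64))
        return [enc_out.tokens_final.data.copy()]

    def __call__(
        self, images: np.ndarray, cached_tokens: list[np.ndarray] | None = None
    ) -> SegPrediction:
        images = np.asarray(images, dtype=np.float64)
        raw = cached_tokens if cached_tokens is not None else self.encode_tokens(images)
        g = self.encoder.cfg.grid_size
        tokens = Tensor(raw[0])
        b = tokens.shape[0]
        x = tokens.reshape(b, g, g, tokens.shape[-1]).transpose(0, 3, 1, 2)
        x = self.in_conv(x).relu()
        for conv in self.up_convs:
            x = conv(nn.upsample2x2(x)).relu()
        return SegPrediction(logits=self.head(x))


# -- losses -----------------------------------------------------------------

def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label values outside [0, num_classes)")
    return np.moveaxis(np.eye(n_classes)[labels], -1, 1)  # (B, C, H, W)


def dice_loss(probs: Tensor, labels: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Soft Dice, per sample, averaged over ALL classes including background.

    Per class c: 1 - (2*sum(p*g) + eps) / (sum(p^2) + sum(g^2) + eps); the
    eps guard makes the term 0 for a class absent from both maps.
    """
    n_classes = probs.shape[1]
    g = _one_hot(labels, n_classes)
    inter = (probs * Tensor(g)).sum(axis=3).sum(axis=2)
    denom = (probs * probs).sum(axis=3).sum(axis=2) + Tensor((g**2).sum(axis=(2, 3)))
    per_class = 1.0 - (2.0 * inter + eps) / (denom + eps)  # (B, C)
    return per_class.mean(axis=1).mean()


def focal_loss(
    probs: Tensor, labels: np.ndarray, gamma: float = 2.0, alpha: float = 0.25
) -> Tensor:
    """Mean over pixels of -alpha * (1 - p_true)^gamma * log(p_true).

    Probabilities are clipped to [1e-8, 1] before the logarithm; the
    clipping is part of the contract.
    """
    labels = np.asarray(labels)
    b, _, h, w = probs.shape
    bi = np.arange(b)[:, None, None]
    ri = np.arange(h)[None, :, None]
    ci = np.arange(w)[None, None, :]
    p_true = probs[bi, labels, ri, ci].clip(1e-8, 1.0)
    return (-alpha * (1.0 - p_true) ** gamma * p_true.log()).mean(axis=2).mean(axis=1).mean()


def ce_pixel_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Pixel-wise multi-class cross-entropy from logits via log-sum-exp."""
    labels = np.asarray(labels)
    logp = logits - logits.logsumexp(axis=1, keepdims=True)
    b, _, h, w = logits.shape
    bi = np.arange(b)[:, None, None]
    ri = np.arange(h)[None, :, None]
    ci = np.arange(w)[None, None, :]
    return (-logp[bi, labels, ri, ci]).mean(axis=2).mean(axis=1).mean()


def hybrid_loss(
    logits: Tensor, labels: np.ndarray, cfg: HybridLossConfig = HybridLossConfig()
) -> Tensor:
    """lambda_dice * Dice + lambda_focal * Focal + lambda_ce * CE."""
    total = Tensor(0.0)
    probs = logits.softmax(axis=1)
    if cfg.lambda_dice:
        total = total + cfg.lambda_dice * dice_loss(probs, labels, cfg.eps)
    if cfg.lambda_focal:
        total = total + cfg.lambda_focal * focal_loss(probs, labels, cfg.gamma, cfg.alpha)
    if cfg.lambda_ce:
        total = total + cfg.lambda_ce * ce_pixel_loss(logits, labels)
    return total


def train_segmenter(
    samples,
    model,
    loss_cfg: HybridLossConfig = HybridLossConfig(),
    seed: int = 0,
    steps: int = 300,
    batch_size: int = 8,
    learning_rate: float = 1e-3,
) -> dict:
    """Train a segmenter (UNet / MAEFUnet / MAEDirect) on labelled slices.

    Only non-frozen parameters are updated, so any frozen encoder inside the
    model is untouched. Deterministic per seed. Returns a checkpoint dict.
    """
    if len(samples) == 0:
        raise ValueError("need at least one labelled slice")
    n_classes = getattr(model, "num_classes", None) or model.cfg.num_classes
    images = np.stack([s.image for s in samples])
    labels = np.stack([np.asarray(s.label_grid, dtype=np.int64) for s in samples])
    if labels.max() >= n_classes:
        raise ValueError(
            f"label value {labels.max()} >= num_classes {n_classes}"
        )
    opt = nn.AdamW(model.parameters(), lr=learning_rate)
    rng = substream(seed, "seg-batches")
    cache = None
    if hasattr(model, "encode_tokens"):
        # frozen encoder: its token maps for a fixed slice set never change,
        # so compute them once instead of every step
        chunks = [
            model.encode_tokens(images[j : j + 32]) for j in range(0, len(images), 32)
        ]
        cache = [np.concatenate(per_layer, axis=0) for per_layer in zip(*chunks)]
    history = []
    for _ in range(steps):
        idx = rng.integers(0, len(samples), size=min(batch_size, len(samples)))
        if cache is None:
            pred = model(images[idx])
        else:
            pred = model(images[idx], cached_tokens=[c[idx] for c in cache])
        loss = hybrid_loss(pred.logits, labels[idx], loss_cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    return {
        "kind": type(model).__name__,
        "seed": seed,
        "state": model.state_dict(),
        "loss_history": history,
    }
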