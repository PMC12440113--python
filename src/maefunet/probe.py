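"""Frozen-encoder linear probing for MRI sequence classification.

The pretrained encoder is used as a fixed feature extractor: the final,
post-normalisation [CLS] embedding feeds a single affine classifier.  With
C classes and embedding dimension d the probe has exactly C*(d+1)
trainable parameters; the encoder contributes none.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .mae import MAEModel
from .nn import Tensor
from .seeding import substream

__all__ = [
    "LinearProbe",
    "ProbeConfig",
    "ce_loss",
    "cls_embedding",
    "eval_accuracy",
    "probe_logits",
    "train_probe",
]


@dataclass(frozen=True)
class ProbeConfig:
    num_classes: int
    embedding_dim: int = 768
    freeze_encoder: bool = True
    learning_rate: float = 1e-4

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")


class LinearProbe(nn.Module):
    """Single affine map: logits = W @ embedding + b."""

    def __init__(self, cfg: ProbeConfig, init_seed: int = 0):
        object.__setattr__(self, "cfg", cfg)
        rng = substream(init_seed, "probe-init")
        self.head = nn.Linear(cfg.embedding_dim, cfg.num_classes, rng)

    def __call__(self, embeddings: np.ndarray | Tensor) -> Tensor:
        if not isinstance(embeddings, Tensor):
            embeddings = Tensor(np.asarray(embeddings, dtype=np.float64))
        return self.head(embeddings)


def cls_embedding(images: np.ndarray, encoder: MAEModel) -> np.ndarray:
    """Final-layer post-norm [CLS] vectors, (B, d). Encoder weights untouched."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.shape[-1] != encoder.cfg.image_size:
        raise ValueError(
            f"image size {images.shape[-2:]} does not match encoder config "
            f"{encoder.cfg.image_size}"
        )
    return encoder.encode(images).cls_embedding.data.copy()


def probe_logits(embedding: np.ndarray, probe: LinearProbe) -> np.ndarray:
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.shape[-1] != probe.cfg.embedding_dim:
        raise ValueError("embedding dimension mismatch")
    return probe(emb).data


def ce_loss(logits: Tensor | np.ndarray, y: np.ndarray) -> Tensor:
    """Multi-class cross-entropy: -z_y + log sum_j exp(z_j), batch mean.

    Computed through a shifted log-sum-exp so large logits cannot overflow.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y))
    b = logits.shape[0]
    z_y = logits[np.arange(b), y]
    lse = logits.logsumexp(axis=-1)
    return (lse - z_y).mean()


def train_probe(
    samples,
    encoder: MAEModel,
    cfg: ProbeConfig,
    seed: int = 0,
    steps: int = 200,
    batch_size: int = 32,
) -> LinearProbe:
    """Train only the affine head with AdamW; the encoder stays frozen.

    Embeddings are extracted once up front (the encoder is fixed), which is
    exactly equivalent to streaming them through the frozen encoder.
    """
    labels = np.array([s.class_label for s in samples])
    if len(labels) == 0:
        raise ValueError("empty training set")
    present = set(labels.tolist())
    missing = set(range(cfg.num_classes)) - present
    if missing:
        warnings.warn(f"classes absent from training set: {sorted(missing)}")
    embeddings = np.concatenate(
        [cls_embedding(np.stack([s.image for s in samples[i : i + 64]]), encoder)
         for i in range(0, len(samples), 64)]
    )
    if cfg.freeze_encoder:
        encoder.freeze()
    probe = LinearProbe(cfg, init_seed=seed)
    opt = nn.AdamW(probe.parameters(), lr=cfg.learning_rate, weight_decay=0.0)
    rng = substream(seed, "probe-batches")
    for _ in range(steps):
        idx = rng.integers(0, len(samples), size=min(batch_size, len(samples)))
        logits = probe(embeddings[idx])
        loss = ce_loss(logits, labels[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
    return probe


def eval_accuracy(
    samples, encoder: MAEModel, probe: LinearProbe
) -> dict:
    """Per-class and overall accuracy; argmax predictions, ties -> lowest index.

    Per-class rows are macro (within-class correct/total); 'overall' is micro
    (pooled correct/total). Classes with no samples are excluded from the
    per-class table.
    """
    if len(samples) == 0:
        raise ValueError("empty evaluation set")
    labels = np.array([s.class_label for s in samples])
    preds = []
    for i in range(0, len(samples), 64):
        emb = cls_embedding(np.stack([s.image for s in samples[i : i + 64]]), encoder)
        preds.append(probe_logits(emb, probe).argmax(axis=-1))
    preds = np.concatenate(preds)
    per_class = {}
    for c in range(probe.cfg.num_classes):
        sel = labels == c
        if sel.sum() == 0:
            continue
        per_class[c] = float((preds[sel] == c).mean())
    return {
        "per_class": per_class,
        "overall": float((preds == labels).mean()),
        "n": int(len(labels)),
    }
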