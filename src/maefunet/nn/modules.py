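"""Neural-network building blocks on top of the autodiff core."""
from __future__ import annotations

import hashlib

import numpy as np

from .tensor import Tensor, concat, conv2d, matmul

__all__ = [
    "Conv2d",
    "ConvBlock",
    "LayerNorm",
    "Linear",
    "Module",
    "MultiHeadAttention",
    "TransformerBlock",
]


class Module:
    """Minimal container: tracks parameters and sub-modules by attribute name."""

    def __setattr__(self, name, value):
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor):
                        yield f"{full}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.size
            for p in self.parameters()
            if p.requires_grad or not trainable_only
        )

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = True
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def weight_digest(self) -> str:
        """SHA-256 over all parameter bytes, in name order (freeze audits)."""
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def _init_weight(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # He-style scaling keeps activations O(1) through relu/gelu stacks
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_init_weight(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        object.__setattr__(self, "eps", eps)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Standard scaled dot-product attention; supports cross-attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, kv_dim: int | None = None):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        kv_dim = dim if kv_dim is None else kv_dim
        object.__setattr__(self, "heads", heads)
        object.__setattr__(self, "head_dim", dim // heads)
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(kv_dim, dim, rng)
        self.v_proj = Linear(kv_dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        return x.reshape(b, n, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, q: Tensor, kv: Tensor | None = None) -> Tensor:
        kv = q if kv is None else kv
        b, n, d = q.shape
        qh = self._split(self.q_proj(q))
        kh = self._split(self.k_proj(kv))
        vh = self._split(self.v_proj(kv))
        scores = matmul(qh, kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = matmul(attn, vh).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.out_proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHA(LN(x)); x + MLP(LN(x)) with GELU."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        pad: int | None = None,
    ):
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(
            _init_weight(rng, (c_out, c_in, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        object.__setattr__(self, "pad", kernel // 2 if pad is None else pad)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class ConvBlock(Module):
    """Two 3x3 convolutions, each followed by a channel norm and ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.norm1 = LayerNorm(c_out)
        self.norm2 = LayerNorm(c_out)

    @staticmethod
    def _norm_nchw(x: Tensor, norm: LayerNorm) -> Tensor:
        # LayerNorm acts on the channel axis: move C last and back
        return norm(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        x = self._norm_nchw(self.conv1(x), self.norm1).relu()
        return self._norm_nchw(self.conv2(x), self.norm2).relu()
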