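"""Building blocks for the attention-exposing vision transformer.

Modules are plain Python objects holding :class:`~wildface.nn.autodiff.Tensor`
parameters; ``named_params()`` walks them recursively so the optimizer and
checkpointing see a flat ``name -> Tensor`` mapping.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, cat, dropout, gelu, layer_norm, softmax


class Module:
    """Tiny parameter container with recursive discovery."""

    def named_params(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value
            elif isinstance(value, Module):
                out.update(value.named_params(prefix=f"{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_params(prefix=f"{name}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.named_params().values():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Standard MSA; exposes the post-softmax attention tensor of each call.

    The attention tensor (batch, heads, tokens, tokens) stays in the autodiff
    graph, so after a backward pass ``attention.grad`` holds the gradient of
    the scalar objective with respect to every attention weight.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        b, t, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b, h, t, hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)  # (b, h, t, t), row-stochastic
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(ctx), attn


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        attn_out, attn = self.attn(self.ln1(x))
        x = x + attn_out
        x = x + self.mlp(self.ln2(x))
        return x, attn


__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "MLP",
    "TransformerBlock",
    "cat",
    "dropout",
    "gelu",
    "softmax",
]
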