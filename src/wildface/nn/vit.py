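"""A small vision transformer backbone that exposes per-layer attention.

The backbone fulfils a simple contract: a forward pass yields one feature
vector per image (the class token after the final layer norm) plus, on
request, the full token-to-token attention matrices of every layer, kept in
the autodiff graph so that gradients with respect to attention weights are
available.  The class-token row of these matrices is what attention-rollout
interpretability consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, cat
from .layers import LayerNorm, Linear, Module, TransformerBlock


@dataclass(frozen=True)
class BackboneConfig:
    image_size: int = 224
    patch_size: int = 16
    dim: int = 768
    depth: int = 12
    n_heads: int = 12
    mlp_ratio: float = 4.0

    @property
    def grid(self) -> tuple[int, int]:
        g = self.image_size // self.patch_size
        return (g, g)

    @property
    def n_patches(self) -> int:
        g = self.grid
        return g[0] * g[1]

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be a multiple of patch_size")


class ViTBackbone(Module):
    """Patchify -> linear embed -> class token -> transformer blocks -> LN."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        patch_dim = 3 * cfg.patch_size**2
        self.patch_embed = Linear(patch_dim, cfg.dim, rng)
        self.cls_token = Tensor(rng.normal(0.0, 0.02, size=(1, 1, cfg.dim)), requires_grad=True)
        self.pos_embed = Tensor(
            rng.normal(0.0, 0.02, size=(1, cfg.n_patches + 1, cfg.dim)), requires_grad=True
        )
        self.blocks = [TransformerBlock(cfg.dim, cfg.n_heads, cfg.mlp_ratio, rng) for _ in range(cfg.depth)]
        self.norm = LayerNorm(cfg.dim)

    # contract metadata
    @property
    def patch_grid(self) -> tuple[int, int]:
        return self.cfg.grid

    @property
    def feature_dim(self) -> int:
        return self.cfg.dim

    @property
    def n_layers(self) -> int:
        return self.cfg.depth

    @property
    def n_heads(self) -> int:
        return self.cfg.n_heads

    def patchify(self, images: np.ndarray) -> np.ndarray:
        """(B, H, W, 3) float images -> (B, n_patches, patch_dim)."""
        b, h, w, c = images.shape
        s = self.cfg.image_size
        if (h, w, c) != (s, s, 3):
            raise ValueError(f"expected input images of shape ({s}, {s}, 3), got ({h}, {w}, {c})")
        p = self.cfg.patch_size
        g = h // p
        x = images.reshape(b, g, p, g, p, c).transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(b, g * g, p * p * c)

    def __call__(self, images: np.ndarray, capture_attn: bool = True) -> tuple[Tensor, list[Tensor]]:
        """Return (features (B, dim), per-layer attention tensors)."""
        patches = Tensor(self.patchify(np.asarray(images, dtype=np.float64)))
        x = self.patch_embed(patches)
        b = x.shape[0]
        cls = self.cls_token
        # broadcast the class token over the batch via an explicit ones matmul-free tile
        cls_tiled = cls * Tensor(np.ones((b, 1, 1)))
        x = cat([cls_tiled, x], axis=1) + self.pos_embed
        attentions: list[Tensor] = []
        for block in self.blocks:
            x, attn = block(x)
            if capture_attn:
                attentions.append(attn)
        x = self.norm(x)
        return x[:, 0, :], attentions


def tiny_test_backbone(
    image_size: int = 32,
    patch_size: int = 8,
    dim: int = 64,
    depth: int = 4,
    n_heads: int = 4,
    seed: int = 0,
) -> ViTBackbone:
    """A desk-scale backbone satisfying the full attention-exposure contract."""
    cfg = BackboneConfig(
        image_size=image_size, patch_size=patch_size, dim=dim, depth=depth, n_heads=n_heads, mlp_ratio=2.0
    )
    return ViTBackbone(cfg, np.random.default_rng(seed))
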