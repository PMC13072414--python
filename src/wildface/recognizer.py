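"""The recognizer: attention-exposing backbone + projection and classifier heads.

Two heads share the backbone's class-token feature.  The classifier path is
``feature -> dropout(0.2) -> FC -> GELU -> dropout(0.3) -> FC -> GELU ->
dropout(0.24) -> output layer`` (layered dropout with decreasing rates as
abstraction increases); the projection path is a two-layer MLP into a
256-dimensional L2-normalized embedding space where the contrastive loss
operates.  GELU is used throughout for transformer-family consistency.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn.autodiff import Tensor, dropout, gelu
from .nn.layers import Linear, Module
from .nn.vit import BackboneConfig, ViTBackbone, tiny_test_backbone


@dataclass
class RecognizerConfig:
    n_classes: int
    feature_dropout: float = 0.2
    classifier_hidden_dims: tuple[int, ...] = (512, 256)
    classifier_dropouts: tuple[float, ...] = (0.3, 0.24)
    projection_dims: tuple[int, ...] = (512, 256)
    feature_dim: int | None = None  # optional guard against backbone mismatch

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        rates = (self.feature_dropout, *self.classifier_dropouts)
        if any(not 0.0 <= r < 1.0 for r in rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if len(self.classifier_dropouts) != len(self.classifier_hidden_dims):
            raise ValueError("one dropout rate per hidden classifier layer is required")
        if len(self.projection_dims) != 2:
            raise ValueError("projection head has exactly two layers (hidden, output)")


@dataclass
class ForwardOutput:
    logits: Tensor  # (B, n_classes)
    embedding: Tensor  # (B, projection_dims[-1]), unit L2 norm
    attentions: list[Tensor]  # per layer, (B, heads, tokens, tokens)


def _l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    sq = (x * x).sum(axis=-1, keepdims=True)
    return x * (sq + eps) ** -0.5


class Recognizer(Module):
    def __init__(self, backbone: ViTBackbone, cfg: RecognizerConfig, rng: np.random.Generator):
        if cfg.feature_dim is not None and cfg.feature_dim != backbone.feature_dim:
            raise ValueError(
                f"configured feature_dim {cfg.feature_dim} != backbone feature dim {backbone.feature_dim}"
            )
        self.backbone = backbone
        self.cfg = cfg
        dim = backbone.feature_dim
        dims = (dim, *cfg.classifier_hidden_dims)
        self.classifier_fcs = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.classifier_out = Linear(dims[-1], cfg.n_classes, rng)
        p_hidden, p_out = cfg.projection_dims
        self.proj_fc1 = Linear(dim, p_hidden, rng)
        self.proj_fc2 = Linear(p_hidden, p_out, rng)

    @property
    def n_classes(self) -> int:
        return self.cfg.n_classes

    def forward(
        self,
        images: np.ndarray,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
        capture_attn: bool = False,
    ) -> ForwardOutput:
        """Run a batch of (B, H, W, 3) model-scale images through both heads.

        ``train_mode`` activates the layered dropout (an rng is then
        required); attention capture can be left off for speed during
        training and evaluation.
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4:
            raise ValueError("expected a batch of images (B, H, W, 3)")
        if train_mode and rng is None:
            raise ValueError("train_mode forward needs an rng for dropout")
        feature, attentions = self.backbone(images, capture_attn=capture_attn)

        x = dropout(feature, self.cfg.feature_dropout, rng, train_mode)
        for fc, rate in zip(self.classifier_fcs, self.cfg.classifier_dropouts):
            x = dropout(gelu(fc(x)), rate, rng, train_mode)
        logits = self.classifier_out(x)

        embedding = _l2_normalize(self.proj_fc2(gelu(self.proj_fc1(feature))))
        return ForwardOutput(logits=logits, embedding=embedding, attentions=attentions)

    __call__ = forward


def build_recognizer(
    backbone_cfg: BackboneConfig | ViTBackbone,
    recog_cfg: RecognizerConfig,
    seed: int = 0,
) -> Recognizer:
    """Construct a recognizer from a backbone config (or prebuilt backbone)."""
    rng = np.random.default_rng(seed)
    backbone = backbone_cfg if isinstance(backbone_cfg, ViTBackbone) else ViTBackbone(backbone_cfg, rng)
    return Recognizer(backbone, recog_cfg, rng)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(recognizer: Recognizer, class_names: list[str], path) -> None:
    """Single-archive checkpoint: weights + configs + class map (npz)."""
    meta = {
        "backbone": asdict(recognizer.backbone.cfg),
        "recognizer": asdict(recognizer.cfg),
        "class_names": list(class_names),
    }
    params = {k: p.data for k, p in recognizer.named_params().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **params)


def load_checkpoint(path) -> tuple[Recognizer, list[str]]:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    bcfg = BackboneConfig(**meta["backbone"])
    rmeta = meta["recognizer"]
    for key in ("classifier_hidden_dims", "classifier_dropouts", "projection_dims"):
        rmeta[key] = tuple(rmeta[key])
    rcfg = RecognizerConfig(**rmeta)
    model = build_recognizer(bcfg, rcfg, seed=0)
    for name, param in model.named_params().items():
        param.data = np.array(archive[name], dtype=np.float64)
    return model, list(meta["class_names"])


__all__ = [
    "RecognizerConfig",
    "ForwardOutput",
    "Recognizer",
    "build_recognizer",
    "tiny_test_backbone",
    "save_checkpoint",
    "load_checkpoint",
]
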