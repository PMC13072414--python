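"""Attention interpretability: gradient-weighted rollout, ROI, insertion AUC.

Class-specific relevance is obtained by rolling residual-corrected attention
matrices through the layers, with each layer's attention first weighted by
the gradient of the target-class score and clamped at zero (so only
positively contributing attention survives), then averaged over heads:

    A_l = mean_heads( relu( dscore/dA_l  *  attention_l ) )
    R_l = row_normalize( A_l + I )
    rollout = R_L @ ... @ R_1

The class-token row of the rollout, restricted to patch tokens, is reshaped
to the patch grid, bilinearly upsampled to image resolution and min-max
normalized.  Gamma correction is a rank-preserving power transform used to
soften (gamma < 1) or sharpen (gamma > 1) the map for different purposes.

The insertion experiment quantifies map quality: starting from a blurred
copy of the image, pixels are restored in descending attention order and the
model's target-class confidence is integrated over the restored fraction
(trapezoid).  A random restoration order gives the chance baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .imutils import gaussian_blur
from .nn.autodiff import softmax
from .training import normalize_batch


@dataclass
class AttentionMap:
    values: np.ndarray  # (H, W) in [0, 1]
    target_class: int
    gamma_applied: float = 1.0


@dataclass
class RoiReport:
    threshold: float
    area_fraction: float
    overlap_with_mask: float | None = None


@dataclass
class InsertionCurve:
    fractions: np.ndarray
    confidences: np.ndarray
    auc: float


def _upsample_bilinear(values: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = size
    im = Image.fromarray(values.astype(np.float32), mode="F")
    return np.asarray(im.resize((w, h), Image.BILINEAR), dtype=np.float64)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        warnings.warn("constant relevance map; returning all zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def rollout_from_matrices(attentions: list[np.ndarray], gradients: list[np.ndarray]) -> np.ndarray:
    """Roll gradient-weighted attention through the layers.

    ``attentions``/``gradients`` are per-layer (heads, T, T) arrays for one
    image; returns the (T, T) rollout matrix.
    """
    tokens = attentions[0].shape[-1]
    rollout = np.eye(tokens)
    for attn, grad in zip(attentions, gradients):
        weighted = np.maximum(grad * attn, 0.0).mean(axis=0)  # mean over heads
        corrected = weighted + np.eye(tokens)  # residual connection
        corrected = corrected / corrected.sum(axis=1, keepdims=True)
        rollout = corrected @ rollout
    return rollout


def gradient_weighted_rollout(recognizer, image: np.ndarray, target_class: int) -> AttentionMap:
    """Class-specific attention map for one model-scale float [0,1] image."""
    if not 0 <= target_class < recognizer.n_classes:
        raise ValueError(f"target_class {target_class} out of range [0, {recognizer.n_classes})")
    batch = normalize_batch(np.asarray(image, dtype=np.float64)[None])
    out = recognizer.forward(batch, train_mode=False, capture_attn=True)
    score = out.logits[(0, target_class)]
    recognizer.zero_grad()
    score.backward()

    attns = [a.data[0] for a in out.attentions]
    grads = [a.grad[0] if a.grad is not None else np.zeros_like(a.data[0]) for a in out.attentions]
    rollout = rollout_from_matrices(attns, grads)
    relevance = rollout[0, 1:]  # class-token row over patch tokens
    grid = recognizer.backbone.patch_grid
    values = _upsample_bilinear(relevance.reshape(grid), image.shape[:2])
    return AttentionMap(values=_minmax(values), target_class=target_class)


def gamma_correct(amap: AttentionMap, gamma: float) -> AttentionMap:
    """Elementwise power transform; preserves the pixel ranking exactly."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return AttentionMap(
        values=amap.values**gamma, target_class=amap.target_class, gamma_applied=gamma
    )


def roi_analysis(
    amap: AttentionMap, threshold: float = 0.30, face_mask: np.ndarray | None = None
) -> RoiReport:
    """Fraction of the image whose attention exceeds ``threshold`` (on the
    min-max normalized map), and its overlap with a ground-truth face mask."""
    above = amap.values > threshold
    area_fraction = float(above.mean())
    overlap = None
    if face_mask is not None:
        if face_mask.shape != amap.values.shape:
            raise ValueError("face_mask and attention map must share a shape")
        n_above = above.sum()
        overlap = float((above & face_mask.astype(bool)).sum() / n_above) if n_above else 0.0
    return RoiReport(threshold=threshold, area_fraction=area_fraction, overlap_with_mask=overlap)


def _confidence(recognizer, image: np.ndarray, target_class: int) -> float:
    out = recognizer.forward(normalize_batch(image[None]), train_mode=False, capture_attn=False)
    return float(softmax(out.logits, axis=-1).data[0, target_class])


def _insertion_with_order(
    recognizer,
    image: np.ndarray,
    order: np.ndarray,
    target_class: int,
    fractions: np.ndarray,
    blur_sigma: float,
) -> InsertionCurve:
    h, w = image.shape[:2]
    total = h * w
    baseline = gaussian_blur(image, blur_sigma)
    flat_img = image.reshape(total, -1)
    flat_base = baseline.reshape(total, -1)
    confidences = []
    for f in fractions:
        k = int(round(f * total))
        restored = flat_base.copy()
        restored[order[:k]] = flat_img[order[:k]]
        confidences.append(_confidence(recognizer, restored.reshape(image.shape), target_class))
    confidences = np.asarray(confidences)
    auc = float(np.trapezoid(confidences, fractions))
    return InsertionCurve(fractions=fractions, confidences=confidences, auc=auc)


def _check_fractions(fractions_grid) -> np.ndarray:
    fractions = np.asarray(
        fractions_grid if fractions_grid is not None else np.linspace(0.0, 1.0, 21), dtype=np.float64
    )
    if fractions.min() < 0 or fractions.max() > 1 or np.any(np.diff(fractions) <= 0):
        raise ValueError("fractions must be increasing within [0, 1]")
    if not np.isclose(fractions[-1], 1.0):
        raise ValueError("fractions grid must include 1.0 (the AUC endpoint)")
    return fractions


def insertion_experiment(
    recognizer,
    image: np.ndarray,
    amap: AttentionMap,
    fractions_grid=None,
    blur_sigma: float = 10.0,
) -> InsertionCurve:
    """Restore pixels in descending attention order (ties by raster order)
    and integrate target-class confidence over the restored fraction."""
    if amap.values.shape != image.shape[:2]:
        raise ValueError("attention map and image must be spatially aligned")
    fractions = _check_fractions(fractions_grid)
    order = np.argsort(-amap.values.ravel(), kind="stable")
    return _insertion_with_order(recognizer, image, order, amap.target_class, fractions, blur_sigma)


def random_insertion_baseline(
    recognizer,
    image: np.ndarray,
    target_class: int,
    rng: np.random.Generator,
    fractions_grid=None,
    blur_sigma: float = 10.0,
) -> InsertionCurve:
    """Insertion curve under a uniformly random pixel order (chance baseline)."""
    fractions = _check_fractions(fractions_grid)
    order = rng.permutation(image.shape[0] * image.shape[1])
    return _insertion_with_order(recognizer, image, order, target_class, fractions, blur_sigma)


def save_overlay(image: np.ndarray, amap: AttentionMap, path) -> None:
    """Write a heatmap overlay PNG (attention in red over the grayscale image)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, interpolation="nearest")
    ax.imshow(amap.values, cmap="jet", alpha=0.45, interpolation="bilinear")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
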