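"""Training-time augmentation: spatial, color, degradation, occlusion, mixing.

All operators take and return float images in [0, 1] (H, W, 3) and draw
every random decision from an explicit ``numpy.random.Generator``, so any
pipeline is reproducible bit-exactly from a seed.  Magnitudes follow the
conventions of the common augmentation toolkits: percent-style limits are
multiplicative factors on the normalized scale, HSV offsets act on the 8-bit
HSV scale, and Gaussian-noise variance is specified on the 0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imutils import gaussian_blur, hsv_to_rgb, resize, rgb_to_hsv
from .schedules import MixingParams


@dataclass
class AugmentConfig:
    crop_size: int = 224
    resize_factor: float = 1.1
    hflip_p: float = 0.5
    # shift/scale/rotate
    ssr_p: float = 0.5
    shift_limit: float = 0.08
    scale_limit: float = 0.10
    rotate_limit: float = 10.0
    # color
    color_choice_p: float = 0.5
    jitter_brightness: float = 0.15
    jitter_contrast: float = 0.15
    jitter_saturation: float = 0.15
    jitter_hue: float = 0.05
    hsv_hue: float = 10.0
    hsv_sat: float = 15.0
    hsv_val: float = 10.0
    bc_p: float = 0.4
    bc_limit: float = 0.15
    # degradation
    degrade_p: float = 0.2
    noise_var: tuple[float, float] = (5.0, 25.0)  # on the 0-255 intensity scale
    blur_kernels: tuple[int, ...] = (3, 5)
    # coarse dropout
    dropout_p: float = 0.3
    holes: tuple[int, int] = (1, 8)
    hole_area: tuple[float, float] = (1.0 / 400.0, 1.0 / 100.0)
    hole_aspect: tuple[float, float] = (0.5, 2.0)
    fill_value: tuple[float, float, float] = (0.5, 0.5, 0.5)  # per-channel dataset mean

    @property
    def resize_target(self) -> int:
        return int(round(self.crop_size * self.resize_factor))

    def __post_init__(self):
        for name in ("hflip_p", "ssr_p", "color_choice_p", "bc_p", "degrade_p", "dropout_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.hole_area[0] > self.hole_area[1]:
            raise ValueError("hole_area min must be <= max")
        if self.crop_size >= self.resize_target:
            raise ValueError("crop_size must be smaller than the resize target")


@dataclass
class MixedBatch:
    """A batch after (possibly) MixUp/CutMix, with soft label weights."""

    images: np.ndarray  # (B, H, W, 3)
    label_weights: np.ndarray  # (B, K), rows on the simplex
    lam: float  # realized mixing coefficient
    mode: str  # "none" | "mixup" | "cutmix"
    mask: np.ndarray | None = None  # (H, W) binary keep-mask, cutmix only
    source_indices: np.ndarray | None = None  # permutation pairing i with j


# ---------------------------------------------------------------------------
# per-image pipelines
# ---------------------------------------------------------------------------


def spatial_pipeline(image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    """Resize to 1.1x, random-crop to the input size, flip, shift/scale/rotate."""
    t, c = cfg.resize_target, cfg.crop_size
    img = resize(image, (t, t))
    y0 = int(rng.integers(0, t - c + 1))
    x0 = int(rng.integers(0, t - c + 1))
    img = img[y0 : y0 + c, x0 : x0 + c]
    if rng.random() < cfg.hflip_p:
        img = img[:, ::-1].copy()
    if rng.random() < cfg.ssr_p:
        shift = rng.uniform(-cfg.shift_limit, cfg.shift_limit, size=2) * c
        scale = 1.0 + rng.uniform(-cfg.scale_limit, cfg.scale_limit)
        angle = rng.uniform(-cfg.rotate_limit, cfg.rotate_limit)
        img = _affine(img, shift, scale, angle)
    return img


def _affine(img: np.ndarray, shift: np.ndarray, scale: float, angle_deg: float) -> np.ndarray:
    theta = np.deg2rad(angle_deg)
    co, sn = np.cos(theta), np.sin(theta)
    fwd = scale * np.array([[co, -sn], [sn, co]])
    inv = np.linalg.inv(fwd)
    center = np.array(img.shape[:2]) / 2.0
    offset = center - inv @ (center + shift)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(img[:, :, ch], inv, offset=offset, order=1, mode="nearest")
    return out


def color_pipeline(image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    """Two-level color policy: one of {jitter, HSV offsets} with probability
    ``color_choice_p``, plus independent brightness/contrast with ``bc_p``."""
    img = image
    if rng.random() < cfg.color_choice_p:
        if rng.random() < 0.5:
            img = _color_jitter(img, rng, cfg)
        else:
            img = _hsv_offsets(img, rng, cfg)
    if rng.random() < cfg.bc_p:
        img = img * (1.0 + rng.uniform(-cfg.bc_limit, cfg.bc_limit))
        img = (img - 0.5) * (1.0 + rng.uniform(-cfg.bc_limit, cfg.bc_limit)) + 0.5
    return np.clip(img, 0.0, 1.0)


def _color_jitter(img: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    img = img * (1.0 + rng.uniform(-cfg.jitter_brightness, cfg.jitter_brightness))
    mean = img.mean()
    img = (img - mean) * (1.0 + rng.uniform(-cfg.jitter_contrast, cfg.jitter_contrast)) + mean
    gray = img.mean(axis=2, keepdims=True)
    sat = 1.0 + rng.uniform(-cfg.jitter_saturation, cfg.jitter_saturation)
    img = gray + (img - gray) * sat
    if cfg.jitter_hue > 0:
        hsv = rgb_to_hsv(np.clip(img, 0, 1))
        hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-cfg.jitter_hue, cfg.jitter_hue)) % 1.0
        img = hsv_to_rgb(hsv)
    return img


def _hsv_offsets(img: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    hsv = rgb_to_hsv(np.clip(img, 0, 1))
    hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-cfg.hsv_hue, cfg.hsv_hue) / 255.0) % 1.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] + rng.uniform(-cfg.hsv_sat, cfg.hsv_sat) / 255.0, 0, 1)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] + rng.uniform(-cfg.hsv_val, cfg.hsv_val) / 255.0, 0, 1)
    return hsv_to_rgb(hsv)


_KERNEL_SIGMA = {3: 0.8, 5: 1.1}  # the usual kernel-size -> Gaussian sigma mapping


def degrade(image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    """With probability ``degrade_p``, apply Gaussian noise or Gaussian blur."""
    if rng.random() >= cfg.degrade_p:
        return image
    if rng.random() < 0.5:
        var = rng.uniform(*cfg.noise_var)
        noisy = image + rng.normal(0.0, np.sqrt(var) / 255.0, size=image.shape)
        return np.clip(noisy, 0.0, 1.0)
    k = int(rng.choice(cfg.blur_kernels))
    return gaussian_blur(image, _KERNEL_SIGMA.get(k, 0.3 * ((k - 1) * 0.5 - 1) + 0.8))


def coarse_dropout(image: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    """With probability ``dropout_p``, mask 1-8 small rectangles (occlusion)."""
    if rng.random() >= cfg.dropout_p:
        return image
    img = image.copy()
    h, w = img.shape[:2]
    total = h * w
    n_holes = int(rng.integers(cfg.holes[0], cfg.holes[1] + 1))
    fill = np.asarray(cfg.fill_value)
    for _ in range(n_holes):
        target = rng.uniform(*cfg.hole_area) * total
        aspect = rng.uniform(*cfg.hole_aspect)
        hh = max(1, int(round(np.sqrt(target * aspect))))
        ww = max(1, int(round(target / hh)))
        hh, ww = min(hh, h), min(ww, w)
        y0 = int(rng.integers(0, h - hh + 1))
        x0 = int(rng.integers(0, w - ww + 1))
        img[y0 : y0 + hh, x0 : x0 + ww] = fill
    return img


def eval_preprocess(image: np.ndarray, cfg: AugmentConfig) -> np.ndarray:
    """Deterministic evaluation preprocessing: resize then center crop."""
    t, c = cfg.resize_target, cfg.crop_size
    img = resize(image, (t, t))
    off = (t - c) // 2
    return img[off : off + c, off : off + c]


# ---------------------------------------------------------------------------
# batch mixing
# ---------------------------------------------------------------------------


def mixup(
    images: np.ndarray,
    onehot_labels: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    lam: float | None = None,
) -> MixedBatch:
    """Global interpolation of a batch with a permuted partner batch.

    One mixing coefficient lambda ~ Beta(alpha, alpha) per batch; images and
    labels are mixed with the same lambda so label weights stay convex.
    """
    _check_mix_args(images, onehot_labels, alpha)
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    perm = rng.permutation(images.shape[0])
    mixed = lam * images + (1.0 - lam) * images[perm]
    weights = lam * onehot_labels + (1.0 - lam) * onehot_labels[perm]
    return MixedBatch(mixed, weights, lam, "mixup", source_indices=perm)


def cutmix(
    images: np.ndarray,
    onehot_labels: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    lam: float | None = None,
) -> MixedBatch:
    """Rectangular patch replacement; label weights use the realized area."""
    _check_mix_args(images, onehot_labels, alpha)
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    perm = rng.permutation(images.shape[0])
    h, w = images.shape[1:3]
    cut_area = (1.0 - lam) * h * w
    aspect = rng.uniform(0.5, 2.0)
    rh = min(h, max(0, int(round(np.sqrt(cut_area * aspect)))))
    rw = min(w, max(0, int(round(cut_area / max(rh, 1)))))
    cy = int(rng.integers(0, h))
    cx = int(rng.integers(0, w))
    y0, y1 = np.clip([cy - rh // 2, cy - rh // 2 + rh], 0, h)
    x0, x1 = np.clip([cx - rw // 2, cx - rw // 2 + rw], 0, w)
    mask = np.ones((h, w))
    mask[y0:y1, x0:x1] = 0.0
    lam_real = float(mask.mean())  # kept fraction, recomputed from the clipped rectangle
    mixed = mask[None, :, :, None] * images + (1.0 - mask[None, :, :, None]) * images[perm]
    weights = lam_real * onehot_labels + (1.0 - lam_real) * onehot_labels[perm]
    return MixedBatch(mixed, weights, lam_real, "cutmix", mask=mask, source_indices=perm)


def apply_mixed_augmentation(
    images: np.ndarray,
    onehot_labels: np.ndarray,
    sched: MixingParams,
    rng: np.random.Generator,
) -> MixedBatch:
    """Apply MixUp or CutMix (50/50) with the scheduled probability and alpha."""
    if sched.prob > 0 and sched.alpha_mix > 0 and rng.random() < sched.prob:
        op = cutmix if rng.random() < 0.5 else mixup
        return op(images, onehot_labels, sched.alpha_mix, rng)
    return MixedBatch(images, onehot_labels.astype(np.float64), 1.0, "none")


def _check_mix_args(images: np.ndarray, onehot_labels: np.ndarray, alpha: float) -> None:
    if alpha <= 0:
        raise ValueError("mixing alpha must be positive")
    if images.shape[0] < 2:
        raise ValueError("mixing needs a batch of at least 2")
    if images.shape[0] != onehot_labels.shape[0]:
        raise ValueError("images and labels disagree on batch size")
    rows = onehot_labels.sum(axis=1)
    if not np.allclose(rows, 1.0):
        raise ValueError("labels must be one-hot (rows summing to 1)")
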