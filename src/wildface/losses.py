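"""Training objectives: supervised contrastive, focal, and their combination.

The total objective is ``L_total = L_focal + alpha * L_supcon`` with the
contrastive weight ``alpha`` supplied by the adaptive schedule.  Both losses
are written on the package's autodiff tensors so gradients flow to the model;
plain numpy arrays are accepted too (handy for tests and oracles) and yield
a float.

The supervised contrastive loss operates on L2-normalized embeddings with a
temperature-scaled cosine-similarity softmax: for each anchor i, positives
P(i) are the other same-label samples and the denominator runs over all
other samples A(i).  Anchors without positives are excluded from the mean;
a batch where no anchor has a positive is defined as loss 0 (with a warning).

The focal loss down-weights easy examples by (1 - p_t)^gamma; for soft
(mixed) targets it is the convex combination of the per-class focal terms
under the target weights, which reduces to the standard form for one-hot
targets.  gamma = 0 with unit class balancing recovers cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn.autodiff import Tensor, softmax

PROB_FLOOR = 1e-12  # probability clamp so log stays finite


@dataclass
class LossConfig:
    tau: float = 0.07  # contrastive temperature
    gamma: float = 2.0  # focal focusing parameter
    alpha_t: np.ndarray | None = None  # per-class balancing factors; None = all 1
    supcon_on_mixed: bool = False  # compute SupCon on mixed batches via argmax labels

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.alpha_t is not None:
            self.alpha_t = np.asarray(self.alpha_t, dtype=np.float64)
            if np.any(self.alpha_t <= 0):
                raise ValueError("alpha_t factors must be positive")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def supcon_loss(embeddings, labels, tau: float = 0.07):
    """Supervised contrastive loss over a batch of unit-norm embeddings.

    Mean over anchors with at least one positive of
    ``-1/|P(i)| * sum_{p in P(i)} log softmax_{a in A(i)}(z_i . z_a / tau)``.
    Returns a Tensor if given Tensors, else a float.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    emb, is_tensor = _as_tensor(embeddings)
    labels = np.asarray(labels)
    b = emb.shape[0]
    if b < 2:
        raise ValueError("supcon_loss needs a batch of at least 2")
    norms = np.linalg.norm(emb.data, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-4):
        raise ValueError("embeddings must be L2-normalized")

    pos = (labels[:, None] == labels[None, :]) & ~np.eye(b, dtype=bool)
    n_pos = pos.sum(axis=1)
    valid = n_pos > 0
    if not valid.any():
        warnings.warn("no anchor has a positive partner; SupCon loss defined as 0")
        zero = Tensor(0.0)
        return zero if is_tensor else 0.0

    sims = (emb @ emb.transpose(1, 0)) * (1.0 / tau)
    # numerically stable log-sum-exp over A(i) (off-diagonal), with a detached shift
    off_diag = ~np.eye(b, dtype=bool)
    shift = np.where(off_diag, sims.data, -np.inf).max(axis=1, keepdims=True)
    expd = (sims - Tensor(shift)).exp() * Tensor(off_diag.astype(np.float64))
    log_denom = expd.sum(axis=1, keepdims=True).log() + Tensor(shift)
    log_prob = sims - log_denom  # (b, b); entry (i, p) = log softmax over A(i)

    weights = np.where(pos, 1.0, 0.0)
    weights[valid] /= n_pos[valid, None]
    per_anchor = (log_prob * Tensor(weights)).sum(axis=1)  # sum_p log_prob / |P(i)|
    anchor_mask = valid.astype(np.float64) / valid.sum()
    loss = -(per_anchor * Tensor(anchor_mask)).sum()
    return loss if is_tensor else float(loss.data)


def focal_loss(logits, target_weights, gamma: float = 2.0, alpha_t=None):
    """Focal loss from logits with one-hot or soft (mixed) target weights.

    Per sample: ``sum_c w_c * [-alpha_c * (1 - p_c)^gamma * log(p_c)]`` with
    p = softmax(logits), averaged over the batch.  Probabilities are clamped
    at 1e-12 so the result is always finite.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    z, is_tensor = _as_tensor(logits)
    w = np.asarray(target_weights, dtype=np.float64)
    if z.shape != w.shape:
        raise ValueError("logits and target_weights must have matching shape")
    b, k = z.shape
    alpha = np.ones(k) if alpha_t is None else np.asarray(alpha_t, dtype=np.float64)
    if alpha.shape != (k,):
        raise ValueError(f"alpha_t must have one factor per class ({k})")
    p = softmax(z, axis=-1).maximum(PROB_FLOOR)
    modulation = (Tensor(np.ones(1)) - p) ** gamma if gamma != 0 else Tensor(np.ones((b, k)))
    per_class = modulation * p.log() * Tensor(-alpha[None, :])
    loss = (per_class * Tensor(w)).sum() * (1.0 / b)
    return loss if is_tensor else float(loss.data)


def total_loss(focal, supcon, alpha_w: float):
    """Weighted combination ``focal + alpha_w * supcon``; returns
    (total, components dict) so the trainer can log both terms."""
    total = focal + alpha_w * supcon
    components = {
        "focal": float(focal.data) if isinstance(focal, Tensor) else float(focal),
        "supcon": float(supcon.data) if isinstance(supcon, Tensor) else float(supcon),
        "alpha_w": float(alpha_w),
    }
    return total, components
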