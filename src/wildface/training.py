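"""The training loop: sampler, augmentation, schedules, losses, optimizer.

Each epoch draws class-balanced batches with replacement (weighted random
sampling), runs the per-image augmentation stack, applies the scheduled
MixUp/CutMix policy, optimizes the combined focal + weighted-contrastive
objective with AdamW, and evaluates on the held-out split.  Test accuracy
and F1 feed back into the adaptive schedules: mixing strength, contrastive
weight, plateau learning-rate halving, and the latching fine-tune cap.

Note the evaluation split doubles as the schedule-driving signal, mirroring
the protocol this trainer implements; pass a separate ``val_ds`` to
:func:`train` to keep the test split untouched by scheduling decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentConfig, apply_mixed_augmentation, coarse_dropout, color_pipeline, degrade, eval_preprocess, spatial_pipeline
from .dataio import LabeledDataset, sample_weights
from .imutils import to_float
from .losses import LossConfig, focal_loss, supcon_loss, total_loss
from .metrics import Metrics, compute_metrics
from .nn.autodiff import Tensor
from .nn.optim import AdamW
from .recognizer import Recognizer
from .schedules import (
    FinetuneGate,
    OptimizerPolicy,
    ScheduleState,
    mix_schedule,
    plateau_lr,
    supcon_weight,
)


@dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 16
    seed: int = 0
    early_stop_patience: int = 15
    eval_every: int = 1
    optimizer: OptimizerPolicy = field(default_factory=OptimizerPolicy)
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    use_supcon: bool = True  # False = cross-entropy-family ablation (focal only)
    use_mixing: bool = True  # False = disable MixUp/CutMix regardless of schedule

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (the contrastive loss needs pairs)")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    test_loss: float
    test_accuracy: float
    test_f1: float
    lr: float
    alpha_mix: float
    p_mix: float
    alpha_supcon: float


def normalize_batch(images: np.ndarray) -> np.ndarray:
    """Map float [0,1] images to the model's [-1, 1] input scale."""
    return images * 2.0 - 1.0


def _augment_image(img: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    img = spatial_pipeline(img, rng, cfg)
    img = color_pipeline(img, rng, cfg)
    img = degrade(img, rng, cfg)
    return coarse_dropout(img, rng, cfg)


def predict_scores(
    recognizer: Recognizer, ds: LabeledDataset, aug_cfg: AugmentConfig, batch_size: int = 32
) -> np.ndarray:
    """Deterministic class-probability scores (eval preprocessing, no dropout)."""
    from .nn.autodiff import softmax  # local to avoid cluttering module surface

    scores = []
    for start in range(0, len(ds), batch_size):
        idx = range(start, min(start + batch_size, len(ds)))
        batch = np.stack([eval_preprocess(to_float(ds.get_image(i)), aug_cfg) for i in idx])
        out = recognizer.forward(normalize_batch(batch), train_mode=False, capture_attn=False)
        scores.append(softmax(out.logits, axis=-1).data)
    return np.concatenate(scores, axis=0)


def evaluate(
    recognizer: Recognizer, ds: LabeledDataset, aug_cfg: AugmentConfig | None = None
) -> Metrics:
    """Deterministic evaluation on a dataset (resize, center crop, normalize)."""
    aug_cfg = aug_cfg or AugmentConfig()
    scores = predict_scores(recognizer, ds, aug_cfg)
    return compute_metrics(scores, ds.labels, recognizer.n_classes)


def _test_loss(scores: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    p_t = np.clip(scores[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(np.mean(-((1.0 - p_t) ** gamma) * np.log(p_t)))


def train(
    recognizer: Recognizer,
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    cfg: TrainConfig,
    val_ds: LabeledDataset | None = None,
) -> tuple[list[EpochRecord], dict]:
    """Train the recognizer; returns (history, best checkpoint state).

    The best checkpoint is the parameter set with the highest monitored F1.
    ``val_ds`` (optional) replaces the test split as the schedule-driving and
    checkpoint-selection signal.
    """
    if train_ds.class_names != test_ds.class_names:
        raise ValueError("train and test datasets must share a class map")
    counts = train_ds.class_counts()
    if np.any(counts == 0):
        missing = [train_ds.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes absent from the training split: {missing}")

    monitor_ds = val_ds if val_ds is not None else test_ds
    policy = cfg.optimizer
    n, k = len(train_ds), train_ds.n_classes
    steps_per_epoch = max(1, -(-n // cfg.batch_size))
    weights = sample_weights(train_ds.labels, k)

    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    sample_rng, aug_rng, mix_rng, drop_rng = (np.random.default_rng(s) for s in seeds)

    params = recognizer.named_params()
    opt = AdamW(params, lr=policy.base_lr, weight_decay=policy.weight_decay)
    gate = FinetuneGate(policy)
    lr = policy.base_lr

    history: list[EpochRecord] = []
    f1_history: list[float] = []
    last_acc: float | None = None
    last_f1: float | None = None
    best = {"f1": -np.inf, "epoch": -1, "params": None}

    for epoch in range(cfg.epochs):
        state = ScheduleState(epoch, test_accuracy=last_acc, test_f1=last_f1)
        mix = mix_schedule(state)
        a_sup = supcon_weight(state) if cfg.use_supcon else 0.0
        opt.lr = lr

        epoch_losses = []
        for _ in range(steps_per_epoch):
            idx = sample_rng.choice(n, size=cfg.batch_size, p=weights)
            imgs = np.stack(
                [_augment_image(to_float(train_ds.get_image(i)), aug_rng, cfg.augment) for i in idx]
            )
            onehot = np.zeros((cfg.batch_size, k))
            onehot[np.arange(cfg.batch_size), train_ds.labels[idx]] = 1.0
            if cfg.use_mixing:
                mixed = apply_mixed_augmentation(imgs, onehot, mix, mix_rng)
            else:
                mixed = apply_mixed_augmentation(imgs, onehot, type(mix)(0.0, 0.0), mix_rng)

            out = recognizer.forward(
                normalize_batch(mixed.images), train_mode=True, rng=drop_rng, capture_attn=False
            )
            l_focal = focal_loss(out.logits, mixed.label_weights, cfg.loss.gamma, cfg.loss.alpha_t)
            if cfg.use_supcon and (mixed.mode == "none" or cfg.loss.supcon_on_mixed):
                supcon_labels = mixed.label_weights.argmax(axis=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # batches without positive pairs yield 0
                    l_supcon = supcon_loss(out.embedding, supcon_labels, cfg.loss.tau)
            else:
                l_supcon = Tensor(0.0)
            loss, _ = total_loss(l_focal, l_supcon, a_sup)
            recognizer.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        scores = predict_scores(recognizer, monitor_ds, cfg.augment)
        m = compute_metrics(scores, monitor_ds.labels, k)
        last_acc, last_f1 = m.accuracy, m.f1
        f1_history.append(m.f1)

        lr = plateau_lr(lr, f1_history, policy)
        lr = gate(ScheduleState(epoch, test_accuracy=last_acc), lr)

        history.append(
            EpochRecord(
                epoch=epoch,
                train_loss=float(np.mean(epoch_losses)),
                test_loss=_test_loss(scores, monitor_ds.labels, cfg.loss.gamma),
                test_accuracy=m.accuracy,
                test_f1=m.f1,
                lr=lr,
                alpha_mix=mix.alpha_mix,
                p_mix=mix.prob,
                alpha_supcon=a_sup,
            )
        )

        if m.f1 > best["f1"]:
            best = {
                "f1": m.f1,
                "epoch": epoch,
                "params": {name: p.data.copy() for name, p in params.items()},
            }
        elif epoch - best["epoch"] >= cfg.early_stop_patience:
            break

    return history, best


def load_best(recognizer: Recognizer, best: dict) -> Recognizer:
    """Restore the best-checkpoint parameters into the recognizer."""
    if best.get("params") is None:
        raise ValueError("no checkpoint stored in the provided state")
    for name, p in recognizer.named_params().items():
        p.data = best["params"][name].copy()
    return recognizer


def export_embeddings(
    recognizer: Recognizer, ds: LabeledDataset, aug_cfg: AugmentConfig | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-sample unit-norm embeddings plus a silhouette separation summary.

    Returns a DataFrame (sample_id, identity, e0..e{D-1}) ready for external
    t-SNE/UMAP tooling, and the silhouette score of the identity labeling.
    """
    from sklearn.metrics import silhouette_score

    aug_cfg = aug_cfg or AugmentConfig()
    rows = []
    for start in range(0, len(ds), 32):
        idx = range(start, min(start + 32, len(ds)))
        batch = np.stack([eval_preprocess(to_float(ds.get_image(i)), aug_cfg) for i in idx])
        out = recognizer.forward(normalize_batch(batch), train_mode=False, capture_attn=False)
        rows.append(out.embedding.data)
    emb = np.concatenate(rows, axis=0)
    df = pd.DataFrame(emb, columns=[f"e{j}" for j in range(emb.shape[1])])
    df.insert(0, "identity", [ds.class_names[label] for label in ds.labels])
    df.insert(0, "sample_id", np.arange(len(ds)))
    if len(np.unique(ds.labels)) >= 2:
        sil = float(silhouette_score(emb, ds.labels))
    else:
        sil = float("nan")
    return df, sil
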