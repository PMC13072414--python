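"""Model/Results facade over the training machinery.

:class:`FaceReid` bundles the datasets, recognizer architecture and training
configuration; :meth:`FaceReid.fit` runs the full adaptive recipe and returns
a :class:`FaceReidResults` carrying the trained weights, per-epoch history,
held-out metrics, and the interpretability toolkit (attention maps, ROI
analysis, insertion curves, embedding export) bound to the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .dataio import LabeledDataset, split_dataset
from .imutils import to_float
from .interpret import (
    AttentionMap,
    InsertionCurve,
    RoiReport,
    gamma_correct,
    gradient_weighted_rollout,
    insertion_experiment,
    random_insertion_baseline,
    roi_analysis,
)
from .metrics import Metrics
from .nn.vit import BackboneConfig
from .recognizer import Recognizer, RecognizerConfig, build_recognizer, save_checkpoint
from .schedules import OptimizerPolicy
from .synthetic import NuisanceRanges, generate_dataset, make_identity_bank
from .training import (
    EpochRecord,
    TrainConfig,
    evaluate,
    export_embeddings,
    load_best,
    normalize_batch,
    train,
)
from .augment import eval_preprocess


class FaceReid:
    """An individual re-identification model bound to train/test splits.

    Parameters
    ----------
    train_ds, test_ds
        Labeled datasets sharing a class map (see :func:`wildface.dataio.split_dataset`).
    backbone_cfg, recognizer_cfg, train_cfg
        Architecture and training configuration; sensible defaults are
        derived from the data when omitted.
    """

    def __init__(
        self,
        train_ds: LabeledDataset,
        test_ds: LabeledDataset,
        backbone_cfg: BackboneConfig | None = None,
        recognizer_cfg: RecognizerConfig | None = None,
        train_cfg: TrainConfig | None = None,
    ):
        self.train_ds = train_ds
        self.test_ds = test_ds
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.recognizer_cfg = recognizer_cfg or RecognizerConfig(n_classes=train_ds.n_classes)
        self.train_cfg = train_cfg or TrainConfig()
        if self.recognizer_cfg.n_classes != train_ds.n_classes:
            raise ValueError("recognizer n_classes must match the dataset class map")

    @classmethod
    def from_dataset(cls, ds: LabeledDataset, test_fraction: float = 1 / 11, seed: int = 0, **kwargs):
        """Group-aware split of a single dataset, then construct the model."""
        train_ds, test_ds = split_dataset(ds, test_fraction, seed=seed)
        return cls(train_ds, test_ds, **kwargs)

    def fit(self, seed: int | None = None) -> "FaceReidResults":
        """Train with the full adaptive recipe and return fitted results."""
        cfg = self.train_cfg if seed is None else replace(self.train_cfg, seed=seed)
        recognizer = build_recognizer(self.backbone_cfg, self.recognizer_cfg, seed=cfg.seed)
        history, best = train(recognizer, self.train_ds, self.test_ds, cfg)
        load_best(recognizer, best)
        metrics = evaluate(recognizer, self.test_ds, cfg.augment)
        return FaceReidResults(self, recognizer, history, metrics, cfg)


class FaceReidResults:
    """Fitted results: trained recognizer, history, metrics, interpretability."""

    def __init__(
        self,
        model: FaceReid,
        recognizer: Recognizer,
        history: list[EpochRecord],
        metrics: Metrics,
        train_cfg: TrainConfig,
    ):
        self.model = model
        self.recognizer = recognizer
        self.history = history
        self.metrics = metrics
        self.train_cfg = train_cfg
        self.class_names = model.train_ds.class_names

    # -- reporting -----------------------------------------------------------
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.history])

    def summary(self) -> str:
        m = self.metrics
        per_class = [
            f"  {name:>12s}  acc={acc:5.3f}  auc={auc:5.3f}"
            for name, acc, auc in zip(self.class_names, m.per_class_accuracy, m.per_class_auc)
        ]
        lines = [
            "Face re-identification results",
            "=" * 46,
            f"identities:        {len(self.class_names)}",
            f"train / test size: {len(self.model.train_ds)} / {len(self.model.test_ds)}",
            f"epochs run:        {len(self.history)} (best F1 at epoch {self.best_epoch})",
            "-" * 46,
            f"test accuracy:     {m.accuracy:.4f}",
            f"test macro-F1:     {m.f1:.4f}",
            f"micro-average AUC: {m.micro_auc:.4f}",
            "-" * 46,
            "per-identity:",
            *per_class,
        ]
        return "\n".join(lines)

    @property
    def best_epoch(self) -> int:
        return int(max(self.history, key=lambda r: r.test_f1).epoch)

    def save(self, path) -> None:
        save_checkpoint(self.recognizer, self.class_names, path)

    # -- embeddings ------------------------------------------------------------
    def export_embeddings(self, ds: LabeledDataset | None = None) -> tuple[pd.DataFrame, float]:
        return export_embeddings(self.recognizer, ds or self.model.test_ds, self.train_cfg.augment)

    # -- interpretability ------------------------------------------------------
    def _model_scale(self, image: np.ndarray) -> np.ndarray:
        return eval_preprocess(to_float(image), self.train_cfg.augment)

    def attention_map(self, image: np.ndarray, target_class: int, gamma: float = 1.0) -> AttentionMap:
        amap = gradient_weighted_rollout(self.recognizer, self._model_scale(image), target_class)
        return gamma_correct(amap, gamma) if gamma != 1.0 else amap

    def roi(self, amap: AttentionMap, threshold: float = 0.30, face_mask=None) -> RoiReport:
        return roi_analysis(amap, threshold=threshold, face_mask=face_mask)

    def insertion(
        self, image: np.ndarray, amap: AttentionMap, fractions_grid=None, blur_sigma: float = 10.0
    ) -> InsertionCurve:
        return insertion_experiment(
            self.recognizer, self._model_scale(image), amap, fractions_grid, blur_sigma
        )

    def random_insertion(
        self,
        image: np.ndarray,
        target_class: int,
        rng: np.random.Generator,
        fractions_grid=None,
        blur_sigma: float = 10.0,
    ) -> InsertionCurve:
        return random_insertion_baseline(
            self.recognizer, self._model_scale(image), target_class, rng, fractions_grid, blur_sigma
        )

    def plot_history(self, ax=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.history_frame()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(df["epoch"], df["train_loss"], label="train loss")
        ax.plot(df["epoch"], df["test_loss"], label="test loss")
        ax2 = ax.twinx()
        ax2.plot(df["epoch"], df["test_accuracy"], color="tab:green", label="test accuracy")
        ax.set_xlabel("epoch")
        ax.legend(loc="upper right")
        return ax


# ---------------------------------------------------------------------------
# desk-scale synthetic benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkSpec:
    """The package's standard desk-scale benchmark: 12 synthetic identities,
    40 images each, rendered at 64 px and classified by a small from-scratch
    transformer.  The learning rate is the standard scale for training small
    transformers from random initialization (the adaptive policies on top are
    unchanged)."""

    n_ids: int = 12
    images_per_id: int = 40
    image_size: int = 64
    images_per_group: int = 5
    epochs: int = 30
    batch_size: int = 16
    base_lr: float = 1e-3
    finetune_lr_cap: float = 3e-4
    #: blur for the insertion-experiment baseline at this resolution, chosen
    #: so the blurred image is uninformative (target confidence near chance);
    #: a baseline that still carries the identity makes insertion insensitive.
    insertion_blur_sigma: float = 20.0


def make_benchmark(
    spec: BenchmarkSpec | None = None, seed: int = 0
) -> tuple[FaceReid, LabeledDataset]:
    """Build the benchmark model (ready to fit) and the full dataset."""
    spec = spec or BenchmarkSpec()
    bank = make_identity_bank(spec.n_ids, seed=seed)
    ds = generate_dataset(
        bank,
        [spec.images_per_id] * spec.n_ids,
        NuisanceRanges(),
        images_per_group=spec.images_per_group,
        seed=seed + 1,
        size=spec.image_size,
    )
    train_ds, test_ds = split_dataset(ds, test_fraction=1 / 11, seed=seed)
    backbone = BackboneConfig(
        image_size=spec.image_size, patch_size=8, dim=64, depth=4, n_heads=4, mlp_ratio=2.0
    )
    recog = RecognizerConfig(n_classes=spec.n_ids)
    policy = OptimizerPolicy(base_lr=spec.base_lr, finetune_lr_cap=spec.finetune_lr_cap)
    aug = AugmentConfig(crop_size=spec.image_size)
    tcfg = TrainConfig(
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        seed=seed,
        optimizer=policy,
        augment=aug,
    )
    return FaceReid(train_ds, test_ds, backbone, recog, tcfg), ds
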