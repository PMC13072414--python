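"""Adaptive training policies driven by epoch and test-set performance.

Four policies steer training: a staged MixUp/CutMix schedule (strength and
application probability rise, then decay, with a high-accuracy override), a
warm-up-then-decay schedule for the supervised-contrastive loss weight (with
accuracy overrides), reduce-on-plateau learning-rate halving monitored on
test F1, and a progressive fine-tuning gate that latches a learning-rate cap
once test accuracy exceeds 90%.

All stage tables are data (module constants / dataclass fields), not code;
`mix_schedule` and `supcon_weight` are pure functions of the schedule state.
Stage intervals are closed on both printed endpoints; epochs are 0-indexed
("epoch < 5" means epochs 0-4).  Accuracy overrides use strict comparison
("exceeded 90%" means > 0.90) and a closed band for the [0.80, 0.90] cap.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ScheduleState:
    """Inputs every adaptive policy sees: epoch plus latest test metrics."""

    epoch: int
    test_accuracy: float | None = None
    test_f1: float | None = None

    def __post_init__(self):
        if self.epoch < 0:
            raise ValueError("epoch must be non-negative")


@dataclass(frozen=True)
class MixingParams:
    alpha_mix: float  # Beta parameter; 0 encodes "mixing off"
    prob: float  # per-batch application probability


@dataclass
class OptimizerPolicy:
    base_lr: float = 3e-5
    weight_decay: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-7
    finetune_lr_cap: float = 1e-5
    finetune_acc_threshold: float = 0.90


#: (first epoch of stage, alpha, probability); stages are contiguous and the
#: last one is open-ended.  Epoch < 5: no mixing; 5-14 warm-up; 15-29
#: reinforcement; 30-44 maintenance; 45-59 convergence; >= 60 fine-tuning.
MIX_STAGES: tuple[tuple[int, float, float], ...] = (
    (0, 0.0, 0.0),
    (5, 0.3, 0.3),
    (15, 0.5, 0.5),
    (30, 0.4, 0.4),
    (45, 0.3, 0.3),
    (60, 0.2, 0.2),
)

#: accuracy override: above this test accuracy, mixing drops to (0.1, 0.1)
MIX_ACC_OVERRIDE = (0.92, 0.1, 0.1)

#: (first epoch of stage, SupCon weight): warm-up then decay
SUPCON_STAGES: tuple[tuple[int, float], ...] = (
    (0, 0.05),
    (10, 0.08),
    (20, 0.06),
    (30, 0.03),
)

SUPCON_HIGH_ACC = (0.90, 0.02)  # accuracy > 0.90 -> weight 0.02
SUPCON_CAP_BAND = (0.80, 0.90, 0.05)  # accuracy in [0.80, 0.90] -> weight capped at 0.05


def _staged(value_table, epoch: int):
    current = value_table[0]
    for stage in value_table:
        if epoch >= stage[0]:
            current = stage
    return current


def mix_schedule(state: ScheduleState) -> MixingParams:
    """Staged MixUp/CutMix parameters with the high-accuracy override.

    The override (accuracy > 0.92 -> alpha 0.1, prob 0.1) is evaluated per
    epoch and never re-enables mixing during the no-mixing opening stage.
    """
    _, alpha, prob = _staged(MIX_STAGES, state.epoch)
    acc = state.test_accuracy
    if prob > 0 and acc is not None and acc > MIX_ACC_OVERRIDE[0]:
        alpha, prob = MIX_ACC_OVERRIDE[1], MIX_ACC_OVERRIDE[2]
    return MixingParams(alpha_mix=alpha, prob=prob)


def supcon_weight(state: ScheduleState) -> float:
    """Warm-up-then-decay contrastive weight with accuracy overrides.

    Overrides apply after staging: accuracy > 0.90 forces 0.02; accuracy in
    [0.80, 0.90] caps the staged value at 0.05.  An absent accuracy behaves
    as below every threshold.
    """
    _, weight = _staged(SUPCON_STAGES, state.epoch)
    acc = state.test_accuracy
    if acc is not None:
        if acc > SUPCON_HIGH_ACC[0]:
            return SUPCON_HIGH_ACC[1]
        lo, hi, cap = SUPCON_CAP_BAND
        if lo <= acc <= hi:
            return min(weight, cap)
    return float(weight)


def plateau_lr(
    current_lr: float,
    monitored_history,
    policy: OptimizerPolicy | None = None,
) -> float:
    """Halve the learning rate when the monitored metric has plateaued.

    ``monitored_history`` is the per-epoch metric (test F1) up to now.  The
    rate is halved when the trailing ``plateau_patience`` epochs brought no
    strict improvement over the best value before them, and never drops
    below ``min_lr``.
    """
    policy = policy or OptimizerPolicy()
    hist = list(monitored_history)
    p = policy.plateau_patience
    if len(hist) < p:
        return current_lr
    reference = max(hist[:-p]) if len(hist) > p else hist[0]
    if max(hist[-p:]) <= reference:
        return max(current_lr * policy.plateau_factor, policy.min_lr)
    return current_lr


def finetune_gate(state: ScheduleState, lr: float, policy: OptimizerPolicy | None = None) -> float:
    """Single-shot fine-tuning cap: above 90% accuracy, lr <= 1e-5.

    Stateless form; the trainer uses :class:`FinetuneGate`, which latches.
    """
    policy = policy or OptimizerPolicy()
    acc = state.test_accuracy
    if acc is not None and acc > policy.finetune_acc_threshold:
        return min(lr, policy.finetune_lr_cap)
    return lr


class FinetuneGate:
    """Latching fine-tune gate: once triggered, the cap applies to all later epochs."""

    def __init__(self, policy: OptimizerPolicy | None = None):
        self.policy = policy or OptimizerPolicy()
        self.active = False

    def __call__(self, state: ScheduleState, lr: float) -> float:
        acc = state.test_accuracy
        if acc is not None and acc > self.policy.finetune_acc_threshold:
            self.active = True
        return min(lr, self.policy.finetune_lr_cap) if self.active else lr
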