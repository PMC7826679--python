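"""Multilabel cross-entropy loss and the four-stage module-wise training protocol.

The network is trained in four stages, each optimizing a subset of modules
with the others frozen (their batch-norm statistics frozen too):

1. backbone fine-tuning;
2. LFA + ADA, backbone fixed;
3. ARL, everything else fixed;
4. joint fine-tuning of the whole model.

The optimizer is SGD with momentum 0.9 and weight decay 5e-4, base learning
rate 1e-3 and an exponential per-epoch decay, mirroring the published
hyperparameter table; iteration counts per stage and the decay factor are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor
from .nn.autograd import softplus
from .nn.optim import SGD, ExponentialDecay
from .relation import FARNet

__all__ = ["TrainConfig", "StagePlan", "multilabel_loss", "make_stage_plan", "train"]


def multilabel_loss(y, logits) -> Tensor:
    """Multilabel binary cross-entropy, summed over labels, mean over batch.

    ``L = Σ_l −[y_l log σ(ŷ_l) + (1−y_l) log(1−σ(ŷ_l))]`` computed in the
    numerically stable form ``softplus(ŷ_l) − y_l ŷ_l``; always ≥ 0.
    """
    y_arr = np.asarray(y, dtype=np.float64)
    if not np.isin(y_arr, (0.0, 1.0)).all():
        raise ValueError("targets must be multi-hot vectors with entries in {0, 1}")
    logits = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, dtype=np.float64))
    if y_arr.shape != logits.shape:
        raise ValueError(f"target shape {y_arr.shape} != logit shape {logits.shape}")
    per_label = softplus(logits) - Tensor(y_arr) * logits
    per_sample = per_label.sum(axis=-1)
    return per_sample.mean() if per_sample.ndim > 0 else per_sample


@dataclass(frozen=True)
class StagePlan:
    """Four stages, each naming the module groups trained in it."""

    stages: tuple[frozenset[str], ...] = (
        frozenset({"backbone"}),
        frozenset({"lfa", "ada"}),
        frozenset({"arl"}),
        frozenset({"backbone", "lfa", "ada", "arl"}),
    )

    def __post_init__(self) -> None:
        if len(self.stages) != 4:
            raise ValueError("the training protocol has exactly 4 stages")

    def trainable(self, stage: int, groups: dict[str, list]) -> list[str]:
        return [name for name in groups if name in self.stages[stage]]

    def frozen(self, stage: int, groups: dict[str, list]) -> list[str]:
        return [name for name in groups if name not in self.stages[stage]]


def make_stage_plan() -> StagePlan:
    """The published protocol: (1) backbone, (2) LFA+ADA, (3) ARL, (4) all."""
    return StagePlan()


@dataclass
class TrainConfig:
    momentum: float = 0.9
    weight_decay: float = 0.0005
    base_lr: float = 0.001
    lr_gamma: float = 0.95  # exponential decay factor per epoch
    batch_size: int = 16
    stage_iterations: tuple[int, int, int, int] = (2000, 1000, 1000, 2000)
    seed: int = 0
    val_evals_per_stage: int = 2  # validation-mAP checkpoints within each stage

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")
        for name in ("momentum", "weight_decay", "base_lr", "lr_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(it < 0 for it in self.stage_iterations):
            raise ValueError("stage iteration counts must be nonnegative")


def _set_stage_modes(model: FARNet, trainable: set[str]) -> None:
    """Train mode (batch statistics) only for the stage's modules."""
    model.eval()
    submodules = {
        "backbone": [model.backbone, model.baseline_head],
        "lfa": [model.lfa],
        "ada": [model.se],
        "arl": [model.arl],
    }
    for name in trainable:
        for module in submodules.get(name, []):
            if module is not None:
                module.train(True)


def _evaluate_map(model: FARNet, images: np.ndarray, y: np.ndarray, baseline: bool = False) -> float:
    from .evaluation import average_precision
    from .nn.autograd import sigmoid as _sig

    if baseline:
        was = model.training
        model.eval()
        try:
            conf = np.concatenate(
                [
                    _sig(model.forward_baseline(images[i : i + 32])).data
                    for i in range(0, len(images), 32)
                ]
            )
        finally:
            model.train(was)
    else:
        conf = model.predict(images)
    aps = [
        average_precision(conf[:, l], y[:, l])
        for l in range(y.shape[1])
        if y[:, l].sum() > 0
    ]
    return float(np.mean(aps)) if aps else float("nan")


def train(
    model: FARNet,
    train_images: np.ndarray,
    train_y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    plan: StagePlan | None = None,
    val_images: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
    stages: tuple[int, ...] = (0, 1, 2, 3),
) -> dict:
    """Run the staged protocol; returns per-stage loss/lr curves.

    Frozen modules keep their parameters (and batch-norm statistics)
    bit-identical across a stage.  When validation data is supplied, the
    parameters of each stage revert to the checkpoint with the best
    validation mAP observed during that stage.  Deterministic given
    ``config.seed``.
    """
    if len(train_images) == 0:
        raise ValueError("training set is empty")
    plan = plan or make_stage_plan()
    rng = np.random.default_rng(config.seed)
    groups = model.module_groups()
    n = len(train_images)
    iters_per_epoch = max(1, n // config.batch_size)
    history: dict = {"stages": []}
    for stage in stages:
        trainable_names = plan.trainable(stage, groups)
        n_iters = config.stage_iterations[stage]
        record = {"stage": stage + 1, "trainable": trainable_names, "loss": [], "lr": [], "val_map": []}
        if not trainable_names or n_iters == 0:
            history["stages"].append(record)
            continue
        params = [p for name in trainable_names for p in groups[name]]
        _set_stage_modes(model, set(trainable_names))
        optimizer = SGD(
            params, lr=config.base_lr, momentum=config.momentum, weight_decay=config.weight_decay
        )
        scheduler = ExponentialDecay(optimizer, config.lr_gamma)
        do_val = val_images is not None and len(val_images) > 0 and config.val_evals_per_stage > 0
        eval_at = (
            set(np.linspace(1, n_iters, config.val_evals_per_stage, dtype=int).tolist())
            if do_val
            else set()
        )
        # stage 1 fine-tunes the backbone through its own pooled linear head
        # (the "Linear" stage of the backbone layout); later stages train
        # through the relation pathway
        use_baseline = stage == 0 and model.lfa is not None
        best = (-np.inf, None)
        for it in range(1, n_iters + 1):
            batch = rng.choice(n, size=min(config.batch_size, n), replace=False)
            optimizer.zero_grad()
            if use_baseline:
                logits = model.forward_baseline(train_images[batch])
            else:
                logits = model(train_images[batch])
            loss = multilabel_loss(train_y[batch], logits)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at stage {stage + 1}, iteration {it} "
                    f"(lr={optimizer.lr:.2e})"
                )
            loss.backward()
            optimizer.step()
            record["loss"].append(float(loss.data))
            record["lr"].append(float(optimizer.lr))
            if it % iters_per_epoch == 0:
                scheduler.step()
            if it in eval_at:
                val_map = _evaluate_map(model, val_images, val_y, baseline=use_baseline)
                record["val_map"].append((it, val_map))
                if val_map > best[0]:
                    best = (val_map, [p.data.copy() for p in params])
                _set_stage_modes(model, set(trainable_names))
        if best[1] is not None:
            for p, data in zip(params, best[1]):
                p.data[...] = data
        history["stages"].append(record)
    model.eval()
    return history
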