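"""Teacher training, dual-teacher distillation, LR schedules, evaluation.

The harness trains small convolutional classifiers with momentum SGD under
one of three learning-rate decline strategies (exponential warmup, piecewise,
cosine; the reference configuration is batch size 16, base rate 0.0037,
exponential warmup). Teachers are trained on hard labels; the student is
then distilled against the two frozen teachers with the scheduled
temperature T(x), loss weight lambda(x), and JS-divergence soft loss from
:mod:`dualdistill.distill`.

A supervised run is the lambda == 1 endpoint of the distillation loop (the
soft term carries zero weight), so baseline and distilled runs with the same
seed share batching, initialisation, and the hard-loss path exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import distill as D
from .data import DatasetSplit, LabeledImage
from .nn import ModelSpec, Sequential, build_model
from .schedules import ScheduleParams, lambda_at, progress_fraction, temperature_at

__all__ = [
    "RunConfig",
    "TrainingHistory",
    "EvalReport",
    "lr_at",
    "train_supervised",
    "distill_student",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]

LR_STRATEGIES = ("exponential_warmup", "piecewise", "cosine")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference configuration (batch 16, base LR 0.0037,
    exponential warmup) at a desk-scale epoch budget; the full-scale budget
    is 60 epochs.
    """

    batch_size: int = 16
    base_lr: float = 0.0037
    lr_strategy: str = "exponential_warmup"
    epochs: int = 15
    warmup_fraction: float = 0.1
    decay_rate: float = 0.96
    momentum: float = 0.9
    schedule: ScheduleParams = dataclasses.field(default_factory=ScheduleParams)
    distill: D.DistillConfig = dataclasses.field(default_factory=D.DistillConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_strategy not in LR_STRATEGIES:
            raise ValueError(
                f"unknown lr_strategy {self.lr_strategy!r}; known: {LR_STRATEGIES}"
            )
        if self.batch_size < 1 or self.base_lr <= 0 or self.epochs < 0:
            raise ValueError("batch_size, base_lr must be positive; epochs >= 0")
        if not (0.0 <= self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must lie in [0, 1)")
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValueError("decay_rate must lie in (0, 1]")


@dataclasses.dataclass
class TrainingHistory:
    """Per-step loss/schedule records plus per-epoch validation accuracy."""

    steps: list[dict] = dataclasses.field(default_factory=list)
    val_accuracy: list[float] = dataclasses.field(default_factory=list)

    def record(self, **kv) -> None:
        self.steps.append(kv)

    def column(self, key: str) -> np.ndarray:
        return np.array([rec[key] for rec in self.steps])

    def write_csv(self, path: str | Path) -> None:
        cols = ("step", "lr", "T", "lam", "l_soft", "l_hard", "total")
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for rec in self.steps:
                fh.write(",".join(repr(rec[c]) for c in cols) + "\n")


@dataclasses.dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray
    per_image_seconds: float


def lr_at(step: int, total_steps: int, cfg: RunConfig) -> float:
    """Learning rate at an optimizer step under the configured strategy.

    * exponential_warmup — linear ramp 0 -> base_lr over the warmup window,
      then a per-epoch exponential staircase base_lr * decay_rate**k;
    * piecewise — base_lr stepped down x0.1 at 1/3 and 2/3 of training;
    * cosine — half-cosine decay base_lr * (1 + cos(pi x)) / 2.
    """
    if total_steps <= 0 or not (0 <= step <= total_steps):
        raise ValueError(f"need 0 <= step <= total_steps, got {step}/{total_steps}")
    x = step / total_steps
    if cfg.lr_strategy == "exponential_warmup":
        warmup_steps = round(cfg.warmup_fraction * total_steps)
        if warmup_steps > 0 and step < warmup_steps:
            return cfg.base_lr * step / warmup_steps
        steps_per_epoch = max(1.0, total_steps / max(1, cfg.epochs))
        epochs_since = math.floor((step - warmup_steps) / steps_per_epoch)
        return cfg.base_lr * cfg.decay_rate**epochs_since
    if cfg.lr_strategy == "piecewise":
        return cfg.base_lr * (1.0 if x < 1 / 3 else 0.1 if x < 2 / 3 else 0.01)
    # cosine
    return cfg.base_lr * (1.0 + math.cos(math.pi * x)) / 2.0


def _stack(items: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([it.image for it in items])
    y = np.array([it.label for it in items], dtype=np.int64)
    return X, y


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def _soft_grad_logits(
    soft_student: np.ndarray, soft_teacher: np.ndarray, T: float
) -> np.ndarray:
    """d JS(teacher, softmax(z/T)) / d z, per sample.

    With q = softmax(z/T) and M = (teacher + q)/2, dJS/dq_j = 0.5 ln(q_j/M_j);
    backprop through the temperature softmax contracts with its Jacobian:
    dJS/dz = (1/T) * q * (g - sum(q * g)).
    """
    q, t = soft_student, soft_teacher
    m = 0.5 * (q + t)
    g = 0.5 * (
        np.log(np.maximum(q, D.PROB_EPSILON)) - np.log(np.maximum(m, D.PROB_EPSILON))
    )
    inner = np.sum(q * g, axis=-1, keepdims=True)
    return (q * (g - inner)) / T


def _run_training(
    model: Sequential,
    split: DatasetSplit,
    cfg: RunConfig,
    teachers: tuple[Sequential, Sequential] | None = None,
    lam_override: float | None = None,
) -> TrainingHistory:
    if not split.train:
        raise ValueError("train partition is empty")
    X, y = _stack(split.train)
    n_classes = model.layers[-1].b.shape[0]
    if y.max() >= n_classes:
        raise ValueError(
            f"label {y.max()} outside the model's {n_classes}-class label space"
        )
    Y = _one_hot(y, n_classes)
    history = TrainingHistory()
    n = len(X)
    steps_per_epoch = math.ceil(n / cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    rng = np.random.default_rng(cfg.seed)
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            bsz = len(idx)
            xprog = progress_fraction(step, total_steps)
            T = temperature_at(xprog, cfg.schedule)
            lam = lambda_at(xprog, cfg.schedule) if lam_override is None else lam_override

            z = model.forward(xb)
            s1 = D.temperature_softmax(z, 1.0)
            l_hard = float(np.mean(-np.sum(yb * np.log(np.maximum(s1, D.PROB_EPSILON)), axis=-1)))
            grad = lam * (s1 - yb)

            l_soft = 0.0
            if teachers is not None:
                t1z = teachers[0].predict_logits(xb)
                t2z = teachers[1].predict_logits(xb)
                soft_teacher = D.combine_teacher_soft_labels(t1z, t2z, T, cfg.distill)
                soft_student = D.temperature_softmax(z, T)
                l_soft = D.js_divergence(soft_teacher, soft_student)
                gsoft = _soft_grad_logits(soft_student, soft_teacher, T)
                if cfg.distill.t_squared_scaling:
                    l_soft *= T * T
                    gsoft = gsoft * (T * T)
                grad = grad + (1.0 - lam) * gsoft
            total = (1.0 - lam) * l_soft + lam * l_hard
            if not math.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss {total} at step {step}; aborting"
                )

            model.backward(grad / bsz)
            lr = lr_at(step, total_steps, cfg)
            model.sgd_step(lr, cfg.momentum)
            history.record(
                step=step, lr=lr, T=T, lam=lam, l_soft=l_soft, l_hard=l_hard, total=total
            )
            step += 1
        if split.val:
            history.val_accuracy.append(evaluate(model, split.val).accuracy)
    return history


def train_supervised(
    spec: ModelSpec, split: DatasetSplit, cfg: RunConfig
) -> tuple[Sequential, TrainingHistory]:
    """Hard-label (cross-entropy) training of a registry model."""
    model = build_model(spec)
    history = _run_training(model, split, cfg, teachers=None, lam_override=1.0)
    return model, history


def distill_student(
    spec: ModelSpec,
    teacher1: Sequential,
    teacher2: Sequential,
    split: DatasetSplit,
    cfg: RunConfig,
    lam_override: float | None = None,
) -> tuple[Sequential, TrainingHistory]:
    """Dual-teacher distillation of a student against two frozen teachers."""
    n1 = teacher1.layers[-1].b.shape[0]
    n2 = teacher2.layers[-1].b.shape[0]
    if not (n1 == n2 == spec.n_classes):
        raise ValueError(
            f"label-space mismatch: teachers have {n1}/{n2} classes, "
            f"student expects {spec.n_classes}"
        )
    model = build_model(spec)
    history = _run_training(
        model, split, cfg, teachers=(teacher1, teacher2), lam_override=lam_override
    )
    return model, history


def evaluate(model: Sequential, items: list[LabeledImage]) -> EvalReport:
    """Accuracy and confusion matrix on a labelled set; timing informational."""
    if not items:
        raise ValueError("cannot evaluate on an empty set")
    X, y = _stack(items)
    n_classes = model.layers[-1].b.shape[0]
    t0 = time.perf_counter()
    logits = model.predict_logits(X)
    elapsed = time.perf_counter() - t0
    pred = logits.argmax(axis=-1)
    conf = _sk_confusion(y, pred, labels=np.arange(n_classes))
    return EvalReport(
        accuracy=float(np.mean(pred == y)),
        confusion=conf,
        per_image_seconds=elapsed / len(items),
    )


def save_checkpoint(
    path: str | Path,
    model: Sequential,
    spec: ModelSpec,
    class_names: list[str] | None = None,
) -> None:
    """Serialize weights plus architecture/label metadata to one .npz file."""
    meta = {
        "architecture": spec.architecture,
        "n_classes": spec.n_classes,
        "input_size": spec.input_size,
        "seed": spec.seed,
        "class_names": class_names or [f"class_{i:02d}" for i in range(spec.n_classes)],
    }
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[Sequential, ModelSpec, list[str]]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = ModelSpec(
        architecture=meta["architecture"],
        n_classes=meta["n_classes"],
        input_size=meta["input_size"],
        seed=meta["seed"],
    )
    model = build_model(spec)
    model.load_state_dict(state)
    return model, spec, list(meta["class_names"])
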