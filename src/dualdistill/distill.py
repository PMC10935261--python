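"""Soft-label fusion and loss functions for dual-teacher distillation.

The method trains a small student network against two signals:

* a *soft* target — the element-wise maximum of the two teachers'
  temperature-scaled predictive distributions (``max_out``), renormalised to
  a probability vector and compared with the student's temperature-scaled
  softmax through the symmetric, bounded Jensen-Shannon divergence; and
* a *hard* target — the one-hot ground-truth label, compared with the
  student's ordinary (T=1) softmax through cross-entropy.

The two are mixed as ``total = (1 - lam) * l_soft + lam * l_hard`` with the
scheduled weight ``lam`` from :mod:`dualdistill.schedules`.

All functions accept a single class vector of shape ``(n,)`` or a batch of
shape ``(b, n)``; batched losses are reduced by the mean over the batch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .schedules import ScheduleParams, T_EPSILON, lambda_at, temperature_at

__all__ = [
    "DistillConfig",
    "LossBreakdown",
    "temperature_softmax",
    "max_out",
    "combine_teacher_soft_labels",
    "kl_divergence",
    "js_divergence",
    "cross_entropy",
    "compute_distill_loss",
]

#: floor applied to probabilities inside logarithms
PROB_EPSILON = 1e-12


@dataclasses.dataclass(frozen=True)
class DistillConfig:
    """Loss-composition switches.

    renormalize_soft_label:
        Divide the fused (max-combined) teacher vector by its sum so the soft
        loss compares two genuine distributions. Disabling it feeds the raw
        max vector (sum >= 1) into JS; kept for ablation only.
    t_squared_scaling:
        Multiply the soft loss by T**2, the classical correction that keeps
        soft-gradient magnitudes comparable across temperatures. Off by
        default: the method as specified uses the unscaled JS value.
    literal_division_mode:
        Diagnostic: divide the probability vectors themselves by T instead of
        temperature-scaling the logits. The results are not distributions
        (they sum to 1/T), so this mode raises rather than returning a loss.
    """

    renormalize_soft_label: bool = True
    t_squared_scaling: bool = False
    literal_division_mode: bool = False


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    """Per-step record of the composed distillation loss."""

    T: float
    lam: float
    l_soft: float
    l_hard: float
    total: float

    def __post_init__(self) -> None:
        recomposed = (1.0 - self.lam) * self.l_soft + self.lam * self.l_hard
        if not np.isclose(self.total, recomposed, rtol=0.0, atol=1e-9):
            raise ValueError(
                f"total {self.total} != (1-lam)*l_soft + lam*l_hard = {recomposed}"
            )


def _as_batch(v: np.ndarray, name: str) -> tuple[np.ndarray, bool]:
    arr = np.asarray(v, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 1-D or 2-D, got shape {arr.shape}")
    return arr, squeeze


def temperature_softmax(logits: np.ndarray, T: float) -> np.ndarray:
    """Softmax of ``logits / T``, computed shift-stably.

    T > 1 flattens the distribution (exposing dark knowledge); T < 1
    sharpens it toward the argmax.
    """
    if not (np.isfinite(T) and T > 0):
        raise ValueError(f"temperature must be positive and finite, got {T}")
    z, squeeze = _as_batch(logits, "logits")
    z = z / max(T, T_EPSILON)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return p[0] if squeeze else p


def max_out(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Element-wise maximum of two class-probability vectors.

    The raw fusion of the two teachers' predictions: each class keeps the
    more confident teacher's probability. The result is not normalised —
    its sum is >= 1 (equality iff p == q).
    """
    pa, sp = _as_batch(p, "p")
    qa, sq = _as_batch(q, "q")
    if pa.shape != qa.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {qa.shape}")
    m = np.maximum(pa, qa)
    return m[0] if (sp and sq) else m


def combine_teacher_soft_labels(
    teacher1_logits: np.ndarray,
    teacher2_logits: np.ndarray,
    T: float,
    config: DistillConfig | None = None,
) -> np.ndarray:
    """Fused dual-teacher soft label at temperature ``T``.

    Temperature-softmaxes each teacher, takes the element-wise maximum, and
    (by default) renormalises to sum 1 so the result is a valid distribution.
    """
    config = config or DistillConfig()
    p1 = temperature_softmax(teacher1_logits, T)
    p2 = temperature_softmax(teacher2_logits, T)
    fused = max_out(p1, p2)
    if config.renormalize_soft_label:
        fused = fused / np.sum(fused, axis=-1, keepdims=True)
    return fused


def _kl_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    # 0 * log(0/q) := 0; probabilities floored inside the log only
    ratio = np.log(np.maximum(p, PROB_EPSILON)) - np.log(np.maximum(q, PROB_EPSILON))
    return np.sum(np.where(p > 0, p * ratio, 0.0), axis=-1)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Relative entropy KL(p || q) = sum p ln(p/q), in nats.

    Zero-probability terms contribute 0; q is floored at ``PROB_EPSILON``
    inside the log so support mismatches yield a large finite value rather
    than infinity.
    """
    pa, _ = _as_batch(p, "p")
    qa, _ = _as_batch(q, "q")
    if pa.shape != qa.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {qa.shape}")
    return float(np.mean(_kl_rows(pa, qa)))


def js_divergence(p1: np.ndarray, p2: np.ndarray) -> float:
    """Jensen-Shannon divergence, in nats: symmetric and bounded by ln 2."""
    a, _ = _as_batch(p1, "p1")
    b, _ = _as_batch(p2, "p2")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    m = 0.5 * (a + b)
    return float(np.mean(0.5 * _kl_rows(a, m) + 0.5 * _kl_rows(b, m)))


def cross_entropy(label: np.ndarray, predict: np.ndarray) -> float:
    """Cross-entropy of a one-hot label against a predicted distribution.

    Equals ``-ln predict[true class]``; ``predict`` is floored at
    ``PROB_EPSILON`` inside the log. Raises if ``label`` is not one-hot —
    this loss serves the hard ground-truth labels only.
    """
    la, _ = _as_batch(label, "label")
    pa, _ = _as_batch(predict, "predict")
    if la.shape != pa.shape:
        raise ValueError(f"shape mismatch: {la.shape} vs {pa.shape}")
    is_one_hot = np.all(np.isin(la, (0.0, 1.0))) and np.all(la.sum(axis=-1) == 1.0)
    if not is_one_hot:
        raise ValueError("label must be one-hot")
    ce = -np.sum(la * np.log(np.maximum(pa, PROB_EPSILON)), axis=-1)
    return float(np.mean(ce))


def compute_distill_loss(
    student_logits: np.ndarray,
    teacher1_logits: np.ndarray,
    teacher2_logits: np.ndarray,
    hard_label: np.ndarray,
    x: float,
    params: ScheduleParams | None = None,
    config: DistillConfig | None = None,
    lam_override: float | None = None,
) -> LossBreakdown:
    """Composed dual-teacher distillation loss at training progress ``x``.

    T and lam come from the sigmoid schedules (``lam_override`` pins the
    mixing weight, e.g. to 1 for a hard-label-only baseline). The soft loss
    is the JS divergence between the fused teacher soft label and the
    student's temperature softmax; the hard loss is cross-entropy against the
    student's T=1 softmax, its true predictive distribution.
    """
    params = params or ScheduleParams()
    config = config or DistillConfig()
    T = temperature_at(x, params)
    lam = lambda_at(x, params) if lam_override is None else float(lam_override)

    if config.literal_division_mode:
        soft_teacher = combine_teacher_soft_labels(
            teacher1_logits, teacher2_logits, 1.0, config
        )
        raise ValueError(
            "literal division of probability vectors by T yields vectors summing "
            f"to {1.0 / T:.4g}, not distributions; JS is undefined on them"
        )

    soft_teacher = combine_teacher_soft_labels(
        teacher1_logits, teacher2_logits, T, config
    )
    soft_student = temperature_softmax(student_logits, T)
    l_soft = js_divergence(soft_teacher, soft_student)
    if config.t_squared_scaling:
        l_soft *= T * T
    l_hard = cross_entropy(hard_label, temperature_softmax(student_logits, 1.0))
    total = (1.0 - lam) * l_soft + lam * l_hard
    return LossBreakdown(T=T, lam=lam, l_soft=l_soft, l_hard=l_hard, total=total)
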