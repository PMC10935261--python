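"""Adaptive decay schedules for dual-teacher distillation.

During distillation two quantities evolve with training progress
``x = step / total_steps``:

* the softmax temperature ``T(x) = scale * sigmoid(steepness * (x - midpoint))``,
  an S-curve rising from ~0 to ~``scale`` (default 3) so the student sees a
  sharp, confident teacher early on and an increasingly soft, dark-knowledge
  rich teacher late in training; and
* the hard-label weight ``lambda(x) = 1 - sigmoid(steepness * (x - midpoint))``,
  the mirror-image S-curve, shifting the loss from ground-truth labels toward
  the fused teacher soft label as training deepens.

Both are built on the same sigmoid, so with default parameters
``T(x)/scale + lambda(x) == 1`` for every x.
"""

from __future__ import annotations

import dataclasses
import math

__all__ = [
    "ScheduleParams",
    "progress_fraction",
    "sigmoid",
    "temperature_at",
    "lambda_at",
]

#: floor applied to the temperature before it is used as a divisor
T_EPSILON = 1e-3


@dataclasses.dataclass(frozen=True)
class ScheduleParams:
    """Constants of the sigmoid schedules.

    Parameters
    ----------
    scale:
        Peak temperature; the temperature curve lives in ``(0, scale)``.
    steepness:
        Slope of the sigmoid; larger values concentrate the transition
        around ``midpoint``.
    midpoint:
        Training-progress fraction at which the transition is centred;
        ``lambda_at(midpoint) == 0.5`` for any steepness.
    literal_temperature_formula:
        If True, evaluate the temperature as ``scale * sigmoid(steepness*x -
        midpoint)`` (the alternative parenthesisation) instead of the default
        ``scale * sigmoid(steepness * (x - midpoint))``. Diagnostics only.
    """

    scale: float = 3.0
    steepness: float = 10.0
    midpoint: float = 0.5
    literal_temperature_formula: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be finite and positive, got {self.scale}")
        if not (math.isfinite(self.steepness) and self.steepness > 0):
            raise ValueError(
                f"steepness must be finite and positive, got {self.steepness}"
            )
        if not (0.0 <= self.midpoint <= 1.0):
            raise ValueError(f"midpoint must lie in [0, 1], got {self.midpoint}")


def sigmoid(z: float) -> float:
    """Numerically stable logistic function 1 / (1 + exp(-z)).

    Branches on the sign of ``z`` so neither branch exponentiates a large
    positive argument; safe for |z| well beyond 700.
    """
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def progress_fraction(step: int, total_steps: int) -> float:
    """Training progress x = step / total_steps, clamped to [0, 1].

    ``step`` counts completed optimizer steps; ``total_steps`` is the total
    number of optimizer steps in the run, so the schedules advance smoothly
    within epochs rather than jumping at epoch boundaries.
    """
    if total_steps <= 0:
        raise ValueError(f"total_steps must be positive, got {total_steps}")
    if step < 0 or step > total_steps:
        raise ValueError(f"step must lie in [0, {total_steps}], got {step}")
    return min(1.0, max(0.0, step / total_steps))


def temperature_at(x: float, params: ScheduleParams | None = None) -> float:
    """Distillation temperature at training progress ``x``.

    Strictly increasing in ``x``, bounded by ``(0, params.scale)``, and
    floored at ``T_EPSILON`` so downstream divisions by T are safe at x ~ 0.
    """
    params = params or ScheduleParams()
    if not math.isfinite(x):
        raise ValueError(f"progress must be finite, got {x}")
    if params.literal_temperature_formula:
        t = params.scale * sigmoid(params.steepness * x - params.midpoint)
    else:
        t = params.scale * sigmoid(params.steepness * (x - params.midpoint))
    return max(t, T_EPSILON)


def lambda_at(x: float, params: ScheduleParams | None = None) -> float:
    """Hard-label loss weight at training progress ``x``.

    Strictly decreasing in ``x``; equals 0.5 exactly at ``x == midpoint``.
    """
    params = params or ScheduleParams()
    if not math.isfinite(x):
        raise ValueError(f"progress must be finite, got {x}")
    return 1.0 - sigmoid(params.steepness * (x - params.midpoint))
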