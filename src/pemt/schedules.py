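"""Time-dependent scalar coefficients used during semi-supervised training.

All schedules are driven by the optimizer iteration counter ``t`` (not
epochs).  The consistency weight ``lambda`` and the uncertainty threshold
``tau`` ramp up sigmoidally so that early, unreliable teacher predictions
carry little weight and few pixels are trusted; the teacher EMA decay
``alpha`` starts at 0 (teacher = copy of student on the first update) and
saturates at its cap; the learning rate decays in steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScheduleState", "lambda_weight", "tau_threshold", "ema_alpha",
           "learning_rate"]


@dataclass(frozen=True)
class ScheduleState:
    """Position within a training run: current and maximum iteration."""

    t: int
    t_max: int

    def __post_init__(self):
        if self.t_max <= 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if not 0 <= self.t <= self.t_max:
            raise ValueError(f"t={self.t} outside [0, {self.t_max}]")


def _check_t(t: float, t_max: float) -> None:
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")


def lambda_weight(t: float, t_max: float, scale: float = 0.1) -> float:
    """Consistency-loss ramp-up weight lambda(t) = scale * exp(-5 (1 - t/t_max)^2).

    Nondecreasing in t; equals `scale` at t = t_max.
    """
    _check_t(t, t_max)
    frac = 1.0 - t / t_max
    return scale * math.exp(-5.0 * frac * frac)


def tau_threshold(t: float, t_max: float) -> float:
    """Uncertainty threshold tau(t) = (0.75 + 0.25 exp(-5 (1 - t/t_max))) * ln 2.

    Ramps from (0.75 + 0.25 e^-5) ln 2 at t=0 up to ln 2 at t = t_max, so the
    consistency mask admits progressively more pixels as the teacher matures.
    """
    _check_t(t, t_max)
    return (0.75 + 0.25 * math.exp(-5.0 * (1.0 - t / t_max))) * math.log(2.0)


def ema_alpha(t: int, cap: float = 0.99) -> float:
    """Teacher EMA decay alpha(t) = min(1 - 1/t, cap), for t >= 1.

    alpha(1) = 0 makes the first teacher update an exact copy of the student.
    """
    if t < 1:
        raise ValueError(f"ema_alpha requires t >= 1, got {t}")
    return min(1.0 - 1.0 / t, cap)


def learning_rate(t: float, lr0: float = 0.01, decay_every: int = 2500,
                  factor: float = 0.1) -> float:
    """Step-decayed learning rate lr0 * factor^floor(t / decay_every)."""
    if lr0 <= 0:
        raise ValueError(f"lr0 must be positive, got {lr0}")
    if decay_every <= 0:
        raise ValueError(f"decay_every must be positive, got {decay_every}")
    return lr0 * factor ** math.floor(t / decay_every)
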