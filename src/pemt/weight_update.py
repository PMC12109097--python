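"""Teacher/student weight coupling: EMA and the perturbation-enhanced pEMA.

The teacher's weights theta* are an exponential moving average of the
student's weights theta:

    theta*_t = alpha * theta*_{t-1} + (1 - alpha) * theta_t            (EMA)

The perturbation-enhanced variant additionally feeds a small residual back
into the student after the teacher update:

    theta_t <- theta_t + beta * mod(theta*_t, theta_t)                 (pEMA)

where ``mod`` is the element-wise floored modulus.  Because a floored
modulus is bounded in magnitude by its divisor, the perturbation each weight
receives is proportional to that weight's own scale, which decouples the two
models without destabilising training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ParameterSet", "floored_mod", "ema_update", "pema_update",
           "perturbation_summary"]


class ParameterSet:
    """A flat, ordered collection of named weight arrays for one network.

    Two ParameterSets are conformable iff their names, order and shapes match
    exactly; EMA/pEMA act elementwise across conformable sets.
    """

    def __init__(self, entries):
        self.entries = [(str(name), np.asarray(arr)) for name, arr in entries]
        for name, arr in self.entries:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in parameter {name!r}")

    @classmethod
    def from_dict(cls, d) -> "ParameterSet":
        return cls(list(d.items()))

    def to_dict(self) -> dict[str, np.ndarray]:
        return dict(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def copy(self) -> "ParameterSet":
        return ParameterSet([(n, a.copy()) for n, a in self.entries])

    def conformable(self, other: "ParameterSet") -> bool:
        return (self.names == other.names and
                all(a.shape == b.shape for (_, a), (_, b) in
                    zip(self.entries, other.entries)))

    def _require_conformable(self, other: "ParameterSet") -> None:
        if not self.conformable(other):
            raise ValueError("ParameterSets are not conformable "
                             "(names, order and shapes must match)")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def allclose(self, other: "ParameterSet", rtol=0.0, atol=0.0) -> bool:
        self._require_conformable(other)
        return all(np.allclose(a, b, rtol=rtol, atol=atol)
                   for (_, a), (_, b) in zip(self.entries, other.entries))

    def equal(self, other: "ParameterSet") -> bool:
        self._require_conformable(other)
        return all(np.array_equal(a, b)
                   for (_, a), (_, b) in zip(self.entries, other.entries))


def floored_mod(a: np.ndarray, b: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Element-wise floored modulus a - b*floor(a/b), guarded near b = 0.

    The result carries the sign of ``b`` and satisfies |result| < |b|.
    Wherever |b| < eps the result is defined as 0 (a near-zero divisor would
    otherwise overflow, and the modulus bound forces a near-zero result
    there anyway).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    tiny = np.abs(b) < eps
    safe_b = np.where(tiny, 1.0, b)
    out = np.mod(a, safe_b)
    return np.where(tiny, np.zeros_like(out), out)


def ema_update(teacher: ParameterSet, student: ParameterSet,
               alpha: float) -> ParameterSet:
    """Exponential moving average: alpha*teacher + (1-alpha)*student."""
    teacher._require_conformable(student)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return ParameterSet([
        (name, alpha * t_arr + (1.0 - alpha) * s_arr)
        for (name, t_arr), (_, s_arr) in zip(teacher.entries, student.entries)
    ])


def pema_update(teacher: ParameterSet, student: ParameterSet, alpha: float,
                beta: float, eps: float = 1e-8) -> tuple[ParameterSet, ParameterSet]:
    """Perturbation-enhanced EMA.

    The teacher update consumes the *unperturbed* student of the current
    step; the student then receives the modulus-residual perturbation
    ``beta * mod(new_teacher, student)``, which becomes the starting point of
    the next gradient step.  Returns ``(new_teacher, perturbed_student)``.
    """
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    new_teacher = ema_update(teacher, student, alpha)
    perturbed = ParameterSet([
        (name, s_arr + beta * floored_mod(t_arr, s_arr, eps))
        for (name, t_arr), (_, s_arr) in zip(new_teacher.entries, student.entries)
    ])
    return new_teacher, perturbed


def perturbation_summary(teacher: ParameterSet, student: ParameterSet,
                         beta: float, eps: float = 1e-8) -> list[dict]:
    """Per-layer magnitude summary of the pEMA perturbation (diagnostics)."""
    teacher._require_conformable(student)
    rows = []
    for (name, t_arr), (_, s_arr) in zip(teacher.entries, student.entries):
        pert = beta * floored_mod(t_arr, s_arr, eps)
        rows.append({
            "name": name,
            "n": int(pert.size),
            "max_abs": float(np.abs(pert).max()),
            "mean_abs": float(np.abs(pert).mean()),
            "rel_to_weight": float(np.abs(pert).mean() /
                                   max(np.abs(s_arr).mean(), 1e-30)),
        })
    return rows
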