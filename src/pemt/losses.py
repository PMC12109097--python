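"""Training objectives: supervised CE+Dice, consistency MSE, and the
uncertainty-masked consistency loss.

The total objective is

    L_total = L_s + lambda(t) * L_u

with L_s = CE + DiceLoss on the labeled batch and L_u the (optionally
uncertainty-masked) mean-squared disagreement between student and teacher
softmax outputs under independent input perturbations.  Gradients flow only
through the student: teacher predictions enter as constants.

All loss functions accept either plain numpy arrays or autodiff
:class:`~pemt._autograd.Tensor` objects for the student prediction; the same
arithmetic builds the backward graph when a Tensor is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor

__all__ = ["LossBundle", "one_hot", "supervised_loss", "consistency_mse",
           "masked_consistency"]

_CLIP = 1e-7


@dataclass
class LossBundle:
    """All scalar loss diagnostics for one training step."""

    supervised: float
    consistency: float
    total: float
    lambda_t: float
    tau_t: float
    masked_fraction: float


def one_hot(label: np.ndarray, num_classes: int) -> np.ndarray:
    """(N, H, W) integer mask -> (N, C, H, W) float32 one-hot encoding."""
    label = np.asarray(label)
    if label.min() < 0 or label.max() >= num_classes:
        raise ValueError(f"label values outside [0, {num_classes - 1}]")
    out = np.zeros((label.shape[0], num_classes) + label.shape[1:], dtype=np.float32)
    for c in range(num_classes):
        out[:, c] = label == c
    return out


def _as_value(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


def supervised_loss(pred, label: np.ndarray, smooth: float = 1e-5):
    """Cross-entropy plus soft Dice loss on a labeled batch.

    ``pred`` is a (N, C, H, W) probability map (Tensor or ndarray);
    ``label`` a (N, H, W) integer mask.  CE is the pixel-mean negative
    log-likelihood; the Dice loss is computed on the soft foreground
    channel(s), per image, averaged over foreground classes, then over the
    batch.  ``smooth`` guards the Dice ratio against empty masks.
    """
    if smooth < 0:
        raise ValueError("smooth must be nonnegative")
    shape = pred.shape if isinstance(pred, Tensor) else np.asarray(pred).shape
    n, c = shape[0], shape[1]
    if np.asarray(label).shape != (n,) + tuple(shape[2:]):
        raise ValueError(f"label shape {np.asarray(label).shape} does not match "
                         f"prediction grid {shape}")
    y = one_hot(label, c)
    if not isinstance(pred, Tensor):
        pred = Tensor(np.asarray(pred))

    n_pixels = float(np.prod(shape[2:]))
    p_safe = pred.clip_min(_CLIP)
    # CE: per-image pixel mean, then batch mean
    ce = -(Tensor(y) * p_safe.log()).sum() * (1.0 / (n * n_pixels))

    # soft Dice over foreground channels, per image
    spatial = tuple(range(2, len(shape)))
    inter = (pred * Tensor(y)).sum(axis=spatial)       # (N, C)
    psum = pred.sum(axis=spatial)
    ysum = y.sum(axis=spatial)
    dice = (inter * 2.0 + smooth) / (psum + Tensor(ysum) + smooth)  # (N, C)
    fg = dice[:, 1:]                                    # drop background channel
    dice_loss = 1.0 - fg.mean()
    return ce + dice_loss


def consistency_mse(p_s, p_t):
    """Plain consistency loss: mean over pixels of the per-pixel
    channel-mean squared difference between student and teacher maps."""
    p_t = p_t.data if isinstance(p_t, Tensor) else np.asarray(p_t)
    shape = p_s.shape if isinstance(p_s, Tensor) else np.asarray(p_s).shape
    if tuple(shape) != p_t.shape:
        raise ValueError(f"grid mismatch: {tuple(shape)} vs {p_t.shape}")
    if not isinstance(p_s, Tensor):
        p_s = Tensor(np.asarray(p_s))
    d = ((p_s - Tensor(p_t)) ** 2.0).mean(axis=1)   # per-pixel channel mean
    return d.mean()


def masked_consistency(p_s, p_t, u: np.ndarray, tau: float):
    """Uncertainty-masked consistency loss.

    Only pixels whose uncertainty ``u`` is strictly below ``tau`` contribute:
    sum(mask * d) / sum(mask), where d is the per-pixel channel-mean squared
    difference.  Returns (loss, masked_fraction); an empty mask yields a
    constant 0 loss.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    p_t = p_t.data if isinstance(p_t, Tensor) else np.asarray(p_t)
    shape = p_s.shape if isinstance(p_s, Tensor) else np.asarray(p_s).shape
    if tuple(shape) != p_t.shape:
        raise ValueError(f"grid mismatch: {tuple(shape)} vs {p_t.shape}")
    u = np.asarray(u)
    expected = (shape[0],) + tuple(shape[2:])
    if u.shape != expected:
        raise ValueError(f"uncertainty map shape {u.shape}, expected {expected}")
    if not isinstance(p_s, Tensor):
        p_s = Tensor(np.asarray(p_s))

    mask = (u < tau).astype(p_t.dtype)
    count = float(mask.sum())
    frac = count / mask.size
    if count == 0.0:
        return Tensor(np.asarray(0.0, dtype=p_t.dtype)), 0.0
    d = ((p_s - Tensor(p_t)) ** 2.0).mean(axis=1)
    loss = (d * Tensor(mask)).sum() * (1.0 / count)
    return loss, frac
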