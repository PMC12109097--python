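"""Per-pixel uncertainty of the teacher from Monte-Carlo forward passes.

The teacher is run K times under stochastic perturbation (dropout active,
fresh additive input noise per pass); the mean softmax output p_bar feeds one
of two uncertainty quantifiers:

* ``rum`` — residual-guided uncertainty map, sum_c p_c (1 - p_c)^(upsilon - p_c),
  a sharply peaked measure around p = 0.5 whose exponent is itself modulated
  by the mean probability;
* ``eum`` — the classical predictive entropy -sum_c p_c log p_c.

Both are ``0`` on one-hot (fully confident) predictions and maximal at the
uniform distribution.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["mc_mean_probability", "rum", "eum", "save_uncertainty_npz",
           "save_uncertainty_png"]


def _check_probability_map(p_bar: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    p_bar = np.asarray(p_bar)
    if p_bar.ndim < 1:
        raise ValueError("probability map must have a class axis")
    if np.any(p_bar < -tol) or np.any(p_bar > 1 + tol):
        raise ValueError("probabilities outside [0, 1]")
    sums = p_bar.sum(axis=-3) if p_bar.ndim >= 3 else p_bar.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("per-pixel class probabilities must sum to 1")
    return p_bar


def mc_mean_probability(model, params, x: np.ndarray, k: int, *,
                        noise_scale: float = 0.1, noise_clip: float = 0.2,
                        seed=None, rng: np.random.Generator | None = None,
                        use_dropout: bool = True,
                        redraw_noise: bool = True) -> np.ndarray:
    """Mean softmax output of K stochastic teacher passes.

    Each pass adds clipped Gaussian input noise (std ``noise_scale``, clipped
    to ±``noise_clip``) and, if ``use_dropout``, samples fresh dropout masks.
    ``redraw_noise=False`` freezes the input noise of the first pass across
    all K passes.  Deterministic given (seed/rng, params, x).

    Returns an array shaped like the model output (N, C, H, W), channel sums 1.
    """
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    dropout_on = use_dropout and model.config.dropout_rate > 0
    if k > 1 and not dropout_on and noise_scale == 0:
        warnings.warn("model has no stochastic element: all K passes are "
                      "identical", stacklevel=2)
    x = np.asarray(x, dtype=np.float32)
    n = x.shape[0]
    # all K passes run as one batched forward: dropout masks differ per pass
    # automatically, and the convolutions amortise into large GEMMs
    if noise_scale > 0:
        if redraw_noise:
            noise = np.clip(rng.normal(0.0, noise_scale, (k,) + x.shape),
                            -noise_clip, noise_clip).astype(np.float32)
        else:
            one = np.clip(rng.normal(0.0, noise_scale, x.shape),
                          -noise_clip, noise_clip).astype(np.float32)
            noise = np.broadcast_to(one, (k,) + x.shape)
        x_rep = (x[None] + noise).reshape((k * n,) + x.shape[1:])
    else:
        x_rep = np.ascontiguousarray(
            np.broadcast_to(x, (k,) + x.shape)).reshape((k * n,) + x.shape[1:])
    probs = model.forward(params, x_rep, stochastic=dropout_on, rng=rng).data
    return probs.reshape((k, n) + probs.shape[1:]).mean(axis=0)


def rum(p_bar: np.ndarray, upsilon: float = 2.0) -> np.ndarray:
    """Residual-guided uncertainty map: sum_c p_c (1 - p_c)^(upsilon - p_c).

    ``p_bar`` has the class axis first after the batch axis, i.e. (..., C, H, W)
    or (C, ...).  ``upsilon`` adjusts the sharpness of the peak at p = 0.5 and
    defaults to 2.  The indeterminate power 0^0 (reachable only when the
    exponent upsilon - p_c hits 0 at p_c in {0, 1}) is taken as 1, the
    continuous limit of (1-p)^(1-p).
    """
    if upsilon <= 0:
        raise ValueError(f"upsilon must be positive, got {upsilon}")
    p_bar = _check_probability_map(p_bar)
    p = np.clip(np.asarray(p_bar, dtype=np.float64), 0.0, 1.0)
    # numpy already defines 0.0**0.0 == 1.0, matching the chosen convention
    term = p * np.power(1.0 - p, upsilon - p)
    axis = -3 if p.ndim >= 3 else 0
    out = term.sum(axis=axis)
    return np.maximum(out, 0.0)


def eum(p_bar: np.ndarray) -> np.ndarray:
    """Entropy uncertainty map -sum_c p_c ln p_c, with 0 ln 0 := 0."""
    p_bar = _check_probability_map(p_bar)
    p = np.clip(np.asarray(p_bar, dtype=np.float64), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0.0, -p * np.log(np.maximum(p, 1e-300)), 0.0)
    axis = -3 if p.ndim >= 3 else 0
    return np.maximum(term.sum(axis=axis), 0.0)


def save_uncertainty_npz(path, u: np.ndarray, **extras) -> None:
    np.savez(path, uncertainty=u, **extras)


def save_uncertainty_png(path, u: np.ndarray, cmap: str = "magma") -> None:
    """Render a single uncertainty map as a heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    u = np.asarray(u)
    if u.ndim != 2:
        raise ValueError("expected a single 2D uncertainty map")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(u, cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
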