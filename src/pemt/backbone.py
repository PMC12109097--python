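"""A small 2D encoder-decoder segmentation network with dropout.

The network is deliberately tiny (default ~4e4 parameters) so that both the
student and teacher can be trained on a single CPU.  It is a plain U-Net:
one group-normalised 3x3 conv + ReLU per encoder level with 2x2
average-pool downsampling, a bottleneck conv, and nearest-upsample +
projected additive skip + conv decoder levels, finished by a 1x1 conv and a
channel softmax.  Dropout sits at the two
deepest levels (bottleneck and deepest decoder) so that Monte-Carlo forward
passes perturb semantic features rather than raw pixels.

The model is *functional*: weights live in a :class:`~pemt.weight_update.ParameterSet`
and are passed into :meth:`UNet2D.forward`, which makes EMA/pEMA coupling and
teacher/student cloning trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import (Tensor, avg_pool2, conv1x1, conv3x3, dropout,
                        group_norm, softmax_channels, upsample2)
from .weight_update import ParameterSet

__all__ = ["BackboneConfig", "UNet2D", "clone_weights"]


@dataclass(frozen=True)
class BackboneConfig:
    in_channels: int = 1
    num_classes: int = 2
    base_width: int = 8
    depth: int = 3
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


class UNet2D:
    """Tiny functional U-Net; serves as both student and teacher."""

    def __init__(self, config: BackboneConfig = BackboneConfig()):
        self.config = config
        c = config
        self.enc_widths = [c.base_width * 2 ** i for i in range(c.depth)]
        self.bottleneck_width = c.base_width * 2 ** c.depth

    # -- parameters ------------------------------------------------------
    def _layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        c = self.config
        shapes: list[tuple[str, tuple[int, ...]]] = []
        def block(name, cout, cin):
            # conv + group-norm gain/offset; normalisation keeps the network
            # scale-invariant in its conv weights, which matters because the
            # modulus weight perturbation inflates magnitudes slightly
            return [(f"{name}.w", (cout, cin, 3, 3)), (f"{name}.b", (cout,)),
                    (f"{name}.g", (cout,)), (f"{name}.gb", (cout,))]

        prev = c.in_channels
        for i, w in enumerate(self.enc_widths):
            shapes += block(f"enc{i}", w, prev)
            prev = w
        shapes += block("bott", self.bottleneck_width, prev)
        prev = self.bottleneck_width
        for i in reversed(range(c.depth)):
            w = self.enc_widths[i]
            # project the upsampled features to the skip width, add the skip,
            # then convolve: an additive-skip U-Net, half the decoder cost of
            # the concatenating form at equal width
            shapes += [(f"up{i}.w", (w, prev)), (f"up{i}.b", (w,))]
            shapes += block(f"dec{i}", w, w)
            prev = w
        shapes += [("head.w", (c.num_classes, prev)), ("head.b", (c.num_classes,))]
        return shapes

    def init_params(self, rng: np.random.Generator) -> ParameterSet:
        """He-initialised weights, zero biases, float32."""
        entries = []
        for name, shape in self._layer_shapes():
            if name.endswith(".b") or name.endswith(".gb"):
                entries.append((name, np.zeros(shape, dtype=np.float32)))
            elif name.endswith(".g"):
                entries.append((name, np.ones(shape, dtype=np.float32)))
            else:
                fan_in = int(np.prod(shape[1:]))
                std = np.sqrt(2.0 / fan_in)
                entries.append(
                    (name, (rng.standard_normal(shape) * std).astype(np.float32)))
        return ParameterSet(entries)

    def num_params(self) -> int:
        return sum(int(np.prod(s)) for _, s in self._layer_shapes())

    # -- forward ---------------------------------------------------------
    def forward(self, params: ParameterSet, x: np.ndarray, *,
                stochastic: bool = False,
                rng: np.random.Generator | None = None,
                requires_grad: bool = False) -> Tensor:
        """Softmax class probabilities for a batch of images.

        `x` is (N, in_channels, H, W) with H and W divisible by 2**depth.
        With ``stochastic=False`` the output is deterministic; with
        ``stochastic=True`` dropout is active and driven by ``rng``.
        Set ``requires_grad=True`` to build the autodiff graph (student).
        """
        c = self.config
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != c.in_channels:
            raise ValueError(f"expected (N, {c.in_channels}, H, W), got {x.shape}")
        if x.shape[2] % 2 ** c.depth or x.shape[3] % 2 ** c.depth:
            raise ValueError(
                f"spatial dims {x.shape[2:]} not divisible by 2^depth={2 ** c.depth}")
        if stochastic and c.dropout_rate > 0 and rng is None:
            raise ValueError("stochastic forward needs an rng")

        p = {name: Tensor(arr, requires_grad=requires_grad)
             for name, arr in params.entries}
        self._last_param_tensors = p  # gradients are read back from here

        def block(h, name):
            h = conv3x3(h, p[f"{name}.w"], p[f"{name}.b"])
            h = group_norm(h, p[f"{name}.g"], p[f"{name}.gb"], groups=4)
            return h.relu()

        h = Tensor(x)
        skips = []
        for i in range(c.depth):
            h = block(h, f"enc{i}")
            skips.append(h)
            h = avg_pool2(h)
        h = block(h, "bott")
        if stochastic and c.dropout_rate > 0:
            h = dropout(h, c.dropout_rate, rng)
        for i in reversed(range(c.depth)):
            h = upsample2(h)
            h = conv1x1(h, p[f"up{i}.w"], p[f"up{i}.b"]) + skips[i]
            h = block(h, f"dec{i}")
            if i == c.depth - 1 and stochastic and c.dropout_rate > 0:
                h = dropout(h, c.dropout_rate, rng)
        logits = conv1x1(h, p["head.w"], p["head.b"])
        return softmax_channels(logits)

    def param_tensors(self) -> dict[str, "Tensor"]:
        """Graph nodes of the most recent forward's parameters.

        Capture this immediately after the forward whose gradients you need:
        a later forward (e.g. a teacher pass) replaces the cache.
        """
        return self._last_param_tensors

    def gradients(self) -> dict[str, np.ndarray]:
        """Parameter gradients accumulated by the last backward pass."""
        return collect_gradients(self._last_param_tensors)


def collect_gradients(param_tensors: dict[str, "Tensor"]) -> dict[str, np.ndarray]:
    return {name: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for name, t in param_tensors.items()}


def clone_weights(params: ParameterSet) -> ParameterSet:
    """Deep, independent copy of a ParameterSet."""
    return params.copy()
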