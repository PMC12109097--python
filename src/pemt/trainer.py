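"""The semi-supervised training loop and its variant switchboard.

Variants form an ablation lattice over the teacher-coupling and the
uncertainty masking:

============  ==================  =====================
variant       teacher update      consistency mask
============  ==================  =====================
supervised    none                (no consistency)
mt            EMA                 none (all pixels)
uamt          EMA                 entropy map (EUM)
uamt_rum      EMA                 residual-guided (RUM)
pemt          pEMA                residual-guided (RUM)
============  ==================  =====================

Each iteration draws equal labeled and unlabeled sub-batches, takes one SGD
step on the student from the CE+Dice plus uncertainty-masked consistency
objective, then applies the variant's teacher/student weight coupling.
Randomness is split into independent named streams (data order, init,
student dropout, input noises, Monte-Carlo passes) so that variants sharing
a seed consume identical draws on the paths they share; this is what makes
the lattice equivalences (e.g. pemt with beta=0 vs uamt_rum) exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from . import losses, schedules, uncertainty
from ._autograd import Tensor
from .backbone import BackboneConfig, UNet2D, clone_weights, collect_gradients
from .metrics import evaluate_masks
from .synthetic_data import Dataset, Pool
from .weight_update import ParameterSet, ema_update, pema_update

__all__ = ["TrainConfig", "TrainState", "TrainResult", "Checkpoint",
           "init_state", "train_step", "fit", "predict", "evaluate_pool",
           "ablate", "save_checkpoint", "load_checkpoint"]

VARIANTS = ("supervised", "mt", "uamt", "uamt_rum", "pemt")

_LOG_FIELDS = ("t", "lr", "lambda", "tau", "supervised", "consistency",
               "masked_fraction", "total")


@dataclass(frozen=True)
class TrainConfig:
    """All hyperparameters, schedules, variant flags and seeds for one run."""

    variant: str = "pemt"
    t_max: int = 6000
    batch_labeled: int = 2
    batch_unlabeled: int = 2
    lr0: float = 0.01
    decay_every: int = 2500
    lr_factor: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-4
    alpha_cap: float = 0.99
    beta: float = 0.001
    upsilon: float = 2.0
    k_passes: int = 8
    noise_scale: float = 0.1
    noise_clip: float = 0.2
    lambda_scale: float = 0.1
    tau_fixed: float | None = None          # overrides the tau(t) schedule
    dice_smooth: float = 1e-5
    mod_eps: float = 1e-8
    consistency_on_labeled: bool = True     # labeled images join the L_u sum
    mc_redraw_noise: bool = True
    teacher_dropout_in_target: bool = False
    augment_rotation: bool = True
    augment_flip: bool = True
    # backbone
    in_channels: int = 1
    num_classes: int = 2
    base_width: int = 8
    depth: int = 3
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.batch_labeled < 1:
            raise ValueError("batch_labeled must be >= 1")

    def backbone_config(self) -> BackboneConfig:
        return BackboneConfig(in_channels=self.in_channels,
                              num_classes=self.num_classes,
                              base_width=self.base_width, depth=self.depth,
                              dropout_rate=self.dropout_rate)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


_STREAMS = ("init", "data", "student_dropout", "noise1", "noise2", "mc")


def _make_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


@dataclass
class TrainState:
    model: UNet2D
    student: ParameterSet
    teacher: ParameterSet
    velocity: dict[str, np.ndarray]
    rngs: dict[str, np.random.Generator]
    t: int = 0


def init_state(config: TrainConfig) -> TrainState:
    rngs = _make_rngs(config.seed)
    model = UNet2D(config.backbone_config())
    student = model.init_params(rngs["init"])
    teacher = clone_weights(student)
    velocity = {name: np.zeros_like(arr) for name, arr in student.entries}
    return TrainState(model=model, student=student, teacher=teacher,
                      velocity=velocity, rngs=rngs, t=0)


def _clipped_noise(rng: np.random.Generator, shape, scale: float,
                   clip: float) -> np.ndarray:
    if scale <= 0:
        return np.zeros(shape, dtype=np.float32)
    return np.clip(rng.normal(0.0, scale, shape), -clip, clip).astype(np.float32)


def _sgd_step(state: TrainState, grads: dict[str, np.ndarray],
              lr: float, config: TrainConfig) -> None:
    new_entries = []
    for name, w in state.student.entries:
        g = grads[name] + config.weight_decay * w
        v = config.momentum * state.velocity[name] + g
        state.velocity[name] = v
        new_entries.append((name, w - np.float32(lr) * v))
    state.student = ParameterSet(new_entries)


def train_step(state: TrainState, labeled_batch, unlabeled_batch, t: int,
               config: TrainConfig) -> tuple[TrainState, losses.LossBundle]:
    """One optimizer iteration: SGD on the student, then teacher coupling.

    ``labeled_batch`` is (images, masks); ``unlabeled_batch`` is an image
    array (possibly empty).  Mutates and returns ``state``.
    """
    x_l, y_l = labeled_batch
    x_l = np.asarray(x_l, dtype=np.float32)
    if x_l.shape[0] == 0:
        raise ValueError("labeled batch must be nonempty")
    x_u = np.asarray(unlabeled_batch, dtype=np.float32)
    n_l = x_l.shape[0]
    x_all = np.concatenate([x_l, x_u]) if x_u.size else x_l

    lam = schedules.lambda_weight(t, config.t_max, config.lambda_scale)
    tau = (config.tau_fixed if config.tau_fixed is not None
           else schedules.tau_threshold(t, config.t_max))

    # student forward on the full batch under noise eta_1, dropout active
    eta1 = _clipped_noise(state.rngs["noise1"], x_all.shape,
                          config.noise_scale, config.noise_clip)
    p_s = state.model.forward(state.student, x_all + eta1, stochastic=True,
                              rng=state.rngs["student_dropout"],
                              requires_grad=True)
    student_tensors = state.model.param_tensors()
    sup = losses.supervised_loss(p_s[:n_l], y_l, smooth=config.dice_smooth)

    if config.variant == "supervised":
        cons = Tensor(np.float32(0.0))
        frac = 1.0
    else:
        x_cons = x_all if config.consistency_on_labeled else x_u
        p_s_cons = p_s if config.consistency_on_labeled else p_s[n_l:]
        eta2 = _clipped_noise(state.rngs["noise2"], x_cons.shape,
                              config.noise_scale, config.noise_clip)
        p_t = state.model.forward(
            state.teacher, x_cons + eta2,
            stochastic=config.teacher_dropout_in_target,
            rng=state.rngs["noise2"] if config.teacher_dropout_in_target else None,
        ).data
        if config.variant == "mt":
            u = np.zeros((x_cons.shape[0],) + x_cons.shape[2:], dtype=np.float32)
        else:
            p_bar = uncertainty.mc_mean_probability(
                state.model, state.teacher, x_cons, config.k_passes,
                noise_scale=config.noise_scale, noise_clip=config.noise_clip,
                rng=state.rngs["mc"], use_dropout=True,
                redraw_noise=config.mc_redraw_noise)
            if config.variant == "uamt":
                u = uncertainty.eum(p_bar)
            else:  # uamt_rum, pemt
                u = uncertainty.rum(p_bar, config.upsilon)
        cons, frac = losses.masked_consistency(p_s_cons, p_t, u, tau)

    total = sup + lam * cons
    total.backward()
    grads = collect_gradients(student_tensors)
    lr = schedules.learning_rate(t, config.lr0, config.decay_every,
                                 config.lr_factor)
    _sgd_step(state, grads, lr, config)

    if config.variant != "supervised":
        alpha = schedules.ema_alpha(t, config.alpha_cap)
        if config.variant == "pemt":
            state.teacher, state.student = pema_update(
                state.teacher, state.student, alpha, config.beta,
                config.mod_eps)
        else:
            state.teacher = ema_update(state.teacher, state.student, alpha)

    state.t = t
    bundle = losses.LossBundle(
        supervised=float(sup.data), consistency=float(cons.data),
        total=float(total.data), lambda_t=lam, tau_t=tau,
        masked_fraction=float(frac))
    return state, bundle


# -- data plumbing -------------------------------------------------------

class _CyclingSampler:
    """Infinite sampler over a pool: shuffled epochs, no repeats within one."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self._order = rng.permutation(n) if n else np.array([], dtype=int)
        self._pos = 0

    def take(self, k: int) -> np.ndarray:
        if self.n == 0 or k == 0:
            return np.array([], dtype=int)
        out = []
        while len(out) < k:
            if self._pos >= self.n:
                self._order = self.rng.permutation(self.n)
                self._pos = 0
            out.append(self._order[self._pos])
            self._pos += 1
        return np.asarray(out)


def _augment(images: np.ndarray, masks: np.ndarray | None,
             rng: np.random.Generator, rotation: bool, flip: bool
             ) -> tuple[np.ndarray, np.ndarray | None]:
    """Random 90-degree rotations and axis flips, applied jointly to image
    and mask. One independent draw per sample."""
    images = images.copy()
    masks = masks.copy() if masks is not None else None
    for i in range(images.shape[0]):
        k = int(rng.integers(4)) if rotation else 0
        fy = bool(rng.integers(2)) if flip else False
        fx = bool(rng.integers(2)) if flip else False
        img = np.rot90(images[i], k, axes=(-2, -1))
        if fy:
            img = img[..., ::-1, :]
        if fx:
            img = img[..., :, ::-1]
        images[i] = img
        if masks is not None:
            m = np.rot90(masks[i], k, axes=(-2, -1))
            if fy:
                m = m[::-1, :]
            if fx:
                m = m[:, ::-1]
            masks[i] = m
    return images, masks


# -- checkpointing --------------------------------------------------------

@dataclass
class Checkpoint:
    config: TrainConfig
    student: ParameterSet
    teacher: ParameterSet
    t: int
    velocity: dict[str, np.ndarray]
    rng_states: dict[str, dict] | None = None


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = ckpt.config.to_yaml()
        f.attrs["t"] = ckpt.t
        if ckpt.rng_states is not None:
            f.attrs["rng_states"] = json.dumps(ckpt.rng_states, default=str)
        for group, entries in (("student", ckpt.student.entries),
                               ("teacher", ckpt.teacher.entries),
                               ("velocity", list(ckpt.velocity.items()))):
            g = f.create_group(group)
            for i, (name, arr) in enumerate(entries):
                d = g.create_dataset(f"p{i}", data=arr)
                d.attrs["name"] = name


def load_checkpoint(path) -> Checkpoint:
    import h5py

    def read_group(g):
        items = sorted(g.keys(), key=lambda s: int(s[1:]))
        return [(g[k].attrs["name"], np.asarray(g[k])) for k in items]

    with h5py.File(path, "r") as f:
        config = TrainConfig.from_yaml(f.attrs["config"])
        rng_states = (json.loads(f.attrs["rng_states"])
                      if "rng_states" in f.attrs else None)
        return Checkpoint(
            config=config,
            student=ParameterSet(read_group(f["student"])),
            teacher=ParameterSet(read_group(f["teacher"])),
            t=int(f.attrs["t"]),
            velocity=dict(read_group(f["velocity"])),
            rng_states=rng_states,
        )


def _rng_states(rngs: dict[str, np.random.Generator]) -> dict[str, dict]:
    return {name: rng.bit_generator.state for name, rng in rngs.items()}


# -- the training loop -----------------------------------------------------

@dataclass
class TrainResult:
    checkpoint: Checkpoint
    log: list[dict]
    val_metrics: dict[str, float] | None = None

    def write_log_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_LOG_FIELDS)
            writer.writeheader()
            writer.writerows(self.log)


def fit(dataset: Dataset, config: TrainConfig,
        log_path=None, checkpoint_path=None) -> TrainResult:
    """Run t = 1..t_max training iterations; fully reproducible given
    ``config.seed``.  Returns the final checkpoint, the per-iteration CSV
    log rows, and end-of-training validation metrics (student network)."""
    if len(dataset.labeled) < 1:
        raise ValueError("dataset needs at least one labeled item")
    state = init_state(config)
    lab_sampler = _CyclingSampler(len(dataset.labeled), state.rngs["data"])
    unl_sampler = _CyclingSampler(len(dataset.unlabeled), state.rngs["data"])
    log: list[dict] = []

    for t in range(1, config.t_max + 1):
        li = lab_sampler.take(config.batch_labeled)
        ui = unl_sampler.take(config.batch_unlabeled)
        x_l, y_l = _augment(dataset.labeled.images[li],
                            dataset.labeled.masks[li], state.rngs["data"],
                            config.augment_rotation, config.augment_flip)
        if len(ui):
            x_u, _ = _augment(dataset.unlabeled.images[ui], None,
                              state.rngs["data"], config.augment_rotation,
                              config.augment_flip)
        else:
            x_u = dataset.unlabeled.images[:0]
        state, bundle = train_step(state, (x_l, y_l), x_u, t, config)
        log.append({
            "t": t,
            "lr": schedules.learning_rate(t, config.lr0, config.decay_every,
                                          config.lr_factor),
            "lambda": bundle.lambda_t, "tau": bundle.tau_t,
            "supervised": bundle.supervised,
            "consistency": bundle.consistency,
            "masked_fraction": bundle.masked_fraction,
            "total": bundle.total,
        })

    ckpt = Checkpoint(config=config, student=state.student,
                      teacher=state.teacher, t=state.t,
                      velocity=state.velocity,
                      rng_states=_rng_states(state.rngs))
    val = evaluate_pool(state.model, state.student, dataset.validation,
                        config.num_classes)
    result = TrainResult(checkpoint=ckpt, log=log, val_metrics=val)
    if log_path is not None:
        result.write_log_csv(log_path)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, ckpt)
    return result


def predict(checkpoint: Checkpoint, images: np.ndarray,
            use_teacher: bool = False) -> list[np.ndarray]:
    """Argmax class masks from a deterministic forward pass."""
    model = UNet2D(checkpoint.config.backbone_config())
    params = checkpoint.teacher if use_teacher else checkpoint.student
    images = np.asarray(images, dtype=np.float32)
    probs = model.forward(params, images, stochastic=False).data
    return [m for m in probs.argmax(axis=1)]


def evaluate_pool(model: UNet2D, params: ParameterSet, pool: Pool,
                  num_classes: int) -> dict[str, float]:
    """Mean per-case metrics of a deterministic forward pass over a pool."""
    masks = pool.masks if pool.masks is not None else pool.hidden_masks
    if masks is None:
        raise ValueError("pool has no ground truth to evaluate against")
    probs = model.forward(params, pool.images, stochastic=False).data
    preds = probs.argmax(axis=1)
    reports = [evaluate_masks(preds[i], masks[i], num_classes)
               for i in range(len(pool))]
    out = {}
    for key in ("dsc", "jac", "hd95", "asd"):
        vals = [getattr(r, key) for r in reports]
        finite = [v for v in vals if math.isfinite(v)]
        out[key] = float(np.mean(finite)) if finite else float("nan")
    return out


def evaluate_cases(checkpoint: Checkpoint, pool: Pool,
                   use_teacher: bool = False) -> list[dict]:
    """Per-case metric rows (case_id, class-macro dsc/jac/hd95/asd)."""
    model = UNet2D(checkpoint.config.backbone_config())
    params = checkpoint.teacher if use_teacher else checkpoint.student
    masks = pool.masks if pool.masks is not None else pool.hidden_masks
    probs = model.forward(params, pool.images, stochastic=False).data
    preds = probs.argmax(axis=1)
    rows = []
    for i in range(len(pool)):
        rep = evaluate_masks(preds[i], masks[i],
                             checkpoint.config.num_classes)
        rows.append({"case_id": int(pool.indices[i]), "dsc": rep.dsc,
                     "jac": rep.jac, "hd95": rep.hd95, "asd": rep.asd})
    return rows


def ablate(dataset: Dataset, base_config: TrainConfig,
           upsilons=(1.0, 2.0, 3.0),
           betas=(0.005, 0.001, 0.0005, 0.0001),
           csv_path=None) -> list[dict]:
    """Sweep the RUM exponent upsilon and the pEMA scale beta.

    The upsilon sweep holds beta at the base config's value; the beta sweep
    holds upsilon at the base value.  Emits one row per run with the
    end-of-training validation metrics."""
    rows = []
    for ups in upsilons:
        cfg = replace(base_config, variant="pemt", upsilon=float(ups))
        res = fit(dataset, cfg)
        rows.append({"parameter": "upsilon", "value": float(ups),
                     **res.val_metrics})
    for beta in betas:
        cfg = replace(base_config, variant="pemt", beta=float(beta))
        res = fit(dataset, cfg)
        rows.append({"parameter": "beta", "value": float(beta),
                     **res.val_metrics})
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["parameter", "value", "dsc", "jac",
                                "hd95", "asd"])
            writer.writeheader()
            writer.writerows(rows)
    return rows
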