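"""Seeded generator of 2D segmentation datasets with fuzzy, noisy boundaries.

The generator emulates the statistical structure that uncertainty-masked
consistency training targets in cardiac MRI: compact foreground structures
(ellipses and annuli — an annulus is a myocardium-like ring around a
ventricle-like disk), strong class imbalance, and boundary ambiguity created
by Gaussian-blurring the class-level intensity image before adding noise.
Interiors are therefore easy while a band around every object boundary mixes
both intensity modes, which is exactly where a trained teacher should be
uncertain.

Every sample is fully determined by ``(spec.seed, index)``, so datasets are
reproducible without storing any files; HDF5 persistence is provided for
interoperability with real cardiac exports (one group per sample holding
``image``, ``mask`` and meta attributes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["DatasetSpec", "SyntheticSample", "Pool", "Dataset",
           "generate_sample", "generate_dataset", "save_dataset_h5",
           "load_dataset_h5", "load_nifti_slices"]


@dataclass(frozen=True)
class DatasetSpec:
    """Configuration for one synthetic dataset.

    ``labeled_fraction`` mirrors the scarce-annotation regime (e.g. 0.05
    means 5% of training images keep their masks).  ``image_size`` must be
    divisible by 2**depth of the backbone that will consume the data.
    """

    n_total: int = 100
    labeled_fraction: float = 0.05
    image_size: int = 64
    n_classes: int = 2
    blob_count_range: tuple[int, int] = (1, 3)
    boundary_blur_sigma: float = 1.5
    noise_sigma: float = 0.1
    bias_field: bool = True
    # per-sample intensity levels are drawn from these ranges, emulating the
    # unstandardized appearance of MRI: a handful of labeled images cannot
    # cover the appearance distribution, which is exactly the regime
    # semi-supervised consistency training targets
    bg_level_range: tuple[float, float] = (0.1, 0.35)
    contrast_range: tuple[float, float] = (0.25, 0.6)
    # per-sample multiplicative jitter on blur and noise, emulating mild
    # acquisition variability across scans
    acquisition_jitter: tuple[float, float] = (0.8, 1.2)
    bias_amplitude: float = 0.2
    # distractors: small structures sharing the foreground intensity but
    # labeled background (bright non-target anatomy); they force the model to
    # use shape/size context rather than intensity alone
    distractor_count_range: tuple[int, int] = (0, 3)
    distractor_radius_range: tuple[float, float] = (0.03, 0.07)
    fg_fraction_bounds: tuple[float, float] = (0.02, 0.5)
    n_val: int = 20
    seed: int = 0

    def __post_init__(self):
        if math.ceil(self.n_total * self.labeled_fraction) < 1:
            raise ValueError("labeled_fraction too small: no labeled images")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must lie in (0, 1]")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4 (cardiac-like mode)")


@dataclass
class SyntheticSample:
    image: np.ndarray          # (H, W) float32 in [0, 1]
    mask: np.ndarray           # (H, W) integer class labels
    meta: dict = field(default_factory=dict)


def _sample_levels(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-sample class intensity levels: background, fg (2-class) or
    background, ring, inner disk, side blob (cardiac-like 4-class)."""
    bg = rng.uniform(*spec.bg_level_range)
    fg = bg + rng.uniform(*spec.contrast_range)
    if spec.n_classes == 2:
        return np.array([bg, fg])
    mid = 0.5 * (bg + fg)
    return np.array([bg, mid, fg, rng.uniform(mid, fg)])


def _ellipse_mask(size: int, rng: np.random.Generator,
                  r_range=(0.10, 0.24)) -> tuple[np.ndarray, tuple]:
    cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
    ry, rx = rng.uniform(r_range[0] * size, r_range[1] * size, size=2)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0, (cy, cx, ry, rx, theta)


def _draw_structures(spec: DatasetSpec, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, list]:
    """Returns (class mask, distractor mask, geometry list)."""
    size = spec.image_size
    mask = np.zeros((size, size), dtype=np.int64)
    lo, hi = spec.blob_count_range
    n_structs = int(rng.integers(lo, hi + 1))
    params = []
    for j in range(n_structs):
        shape_kind = rng.choice(["ellipse", "annulus"])
        ell, geom = _ellipse_mask(size, rng, r_range=(0.14, 0.28))
        if spec.n_classes == 2:
            if shape_kind == "annulus":
                inner, _ = _shrunk(ell, geom, size, rng)
                mask[ell & ~inner] = 1
            else:
                mask[ell] = 1
        else:
            # cardiac-like: first structure is a ring (1) around a disk (2),
            # later structures are side blobs (3)
            if j == 0:
                inner, _ = _shrunk(ell, geom, size, rng)
                mask[ell & ~inner] = 1
                mask[inner] = 2
            else:
                mask[ell & (mask == 0)] = 3
        params.append((shape_kind, geom))
    dlo, dhi = spec.distractor_count_range
    distractor = np.zeros((size, size), dtype=bool)
    for _ in range(int(rng.integers(dlo, dhi + 1))):
        blob, geom = _ellipse_mask(size, rng,
                                   r_range=spec.distractor_radius_range)
        distractor |= blob & (mask == 0)
        params.append(("distractor", geom))
    return mask, distractor, params


def _shrunk(ell: np.ndarray, geom, size: int,
            rng: np.random.Generator) -> tuple[np.ndarray, tuple]:
    cy, cx, ry, rx, theta = geom
    factor = rng.uniform(0.4, 0.65)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    inner = (u / (ry * factor)) ** 2 + (v / (rx * factor)) ** 2 <= 1.0
    return inner, (cy, cx, ry * factor, rx * factor, theta)


def generate_sample(spec: DatasetSpec, index: int) -> SyntheticSample:
    """Render one image/mask pair, fully determined by (spec.seed, index).

    The intensity image is the class-level image blurred by
    ``boundary_blur_sigma`` (fuzzy boundaries), plus additive Gaussian noise
    and an optional smooth multiplicative bias field, clipped to [0, 1].
    Structures are redrawn (same stream) until the foreground fraction falls
    inside ``fg_fraction_bounds``.
    """
    rng = np.random.default_rng([abs(int(spec.seed)), int(index)])
    lo, hi = spec.fg_fraction_bounds
    for _ in range(50):
        mask, distractor, params = _draw_structures(spec, rng)
        fg = float((mask > 0).mean())
        if lo <= fg <= hi:
            break
    levels = _sample_levels(spec, rng)
    image = np.take(levels, mask)
    image[distractor] = levels[-1] if spec.n_classes == 2 else levels[2]
    jitter_blur, jitter_noise = rng.uniform(*spec.acquisition_jitter, size=2)
    if spec.boundary_blur_sigma > 0:
        image = ndimage.gaussian_filter(image,
                                        spec.boundary_blur_sigma * jitter_blur)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma * jitter_noise,
                                   image.shape)
    if spec.bias_field:
        bias = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, image.shape), spec.image_size / 4)
        bias = bias / max(np.abs(bias).max(), 1e-12)
        image = image * (1.0 + spec.bias_amplitude * bias)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(image=image, mask=mask.astype(np.int64),
                           meta={"seed": spec.seed, "index": int(index),
                                 "structures": params, "fg_fraction": fg})


@dataclass
class Pool:
    """A pool of samples. For the unlabeled pool, ground truth is kept only
    under ``hidden_masks`` for evaluation/diagnostics — training code must not
    touch it (``masks`` is None there)."""

    images: np.ndarray                 # (N, 1, H, W) float32
    masks: np.ndarray | None           # (N, H, W) int64, None if unlabeled
    indices: np.ndarray
    hidden_masks: np.ndarray | None = None

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class Dataset:
    labeled: Pool
    unlabeled: Pool
    validation: Pool
    spec: DatasetSpec


def _stack(samples: list[SyntheticSample]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples])[:, None, :, :]
    masks = np.stack([s.mask for s in samples])
    return imgs.astype(np.float32), masks


def generate_dataset(spec: DatasetSpec) -> Dataset:
    """Split ``n_total`` training samples into labeled/unlabeled pools plus a
    disjoint validation pool (indices ``n_total .. n_total + n_val - 1``)."""
    n_labeled = math.ceil(spec.n_total * spec.labeled_fraction)
    split_rng = np.random.default_rng([abs(int(spec.seed)), 998877])
    order = split_rng.permutation(spec.n_total)
    labeled_idx = np.sort(order[:n_labeled])
    unlabeled_idx = np.sort(order[n_labeled:])

    train = [generate_sample(spec, i) for i in range(spec.n_total)]
    val = [generate_sample(spec, spec.n_total + i) for i in range(spec.n_val)]

    li, lm = _stack([train[i] for i in labeled_idx])
    vi, vm = _stack(val)
    if len(unlabeled_idx):
        ui, um = _stack([train[i] for i in unlabeled_idx])
    else:
        h = spec.image_size
        ui = np.zeros((0, 1, h, h), dtype=np.float32)
        um = np.zeros((0, h, h), dtype=np.int64)
    return Dataset(
        labeled=Pool(images=li, masks=lm, indices=labeled_idx),
        unlabeled=Pool(images=ui, masks=None, indices=unlabeled_idx,
                       hidden_masks=um),
        validation=Pool(images=vi, masks=vm,
                        indices=np.arange(spec.n_total,
                                          spec.n_total + spec.n_val)),
        spec=spec,
    )


# -- HDF5 persistence ---------------------------------------------------

def save_dataset_h5(path, dataset: Dataset) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for key in ("n_total", "labeled_fraction", "image_size", "n_classes",
                    "boundary_blur_sigma", "noise_sigma", "n_val", "seed"):
            f.attrs[key] = getattr(dataset.spec, key)
        for name, pool in (("labeled", dataset.labeled),
                           ("unlabeled", dataset.unlabeled),
                           ("validation", dataset.validation)):
            g = f.create_group(name)
            g.create_dataset("images", data=pool.images)
            g.create_dataset("indices", data=pool.indices)
            if pool.masks is not None:
                g.create_dataset("masks", data=pool.masks)
            if pool.hidden_masks is not None:
                g.create_dataset("hidden_masks", data=pool.hidden_masks)


def load_nifti_slices(image_path, mask_path=None, axis: int = 2,
                      normalize: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    """Extract 2D slices from a NIfTI volume (real-data path).

    Returns (images, masks) with images shaped (n_slices, 1, H, W) float32,
    intensity-normalised to [0, 1] per volume if ``normalize``; masks are
    integer arrays or None if no mask volume is given.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(image_path)).dataobj).astype(np.float64)
    vol = np.moveaxis(vol, axis, 0)
    if normalize:
        lo, hi = vol.min(), vol.max()
        vol = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
    images = vol[:, None, :, :].astype(np.float32)
    masks = None
    if mask_path is not None:
        m = np.asanyarray(nib.load(str(mask_path)).dataobj)
        masks = np.moveaxis(m, axis, 0).astype(np.int64)
        if masks.shape != vol.shape:
            raise ValueError("image and mask volumes differ in shape")
    return images, masks


def load_dataset_h5(path) -> Dataset:
    import h5py

    with h5py.File(path, "r") as f:
        spec = DatasetSpec(
            n_total=int(f.attrs["n_total"]),
            labeled_fraction=float(f.attrs["labeled_fraction"]),
            image_size=int(f.attrs["image_size"]),
            n_classes=int(f.attrs["n_classes"]),
            boundary_blur_sigma=float(f.attrs["boundary_blur_sigma"]),
            noise_sigma=float(f.attrs["noise_sigma"]),
            n_val=int(f.attrs["n_val"]),
            seed=int(f.attrs["seed"]),
        )
        pools = {}
        for name in ("labeled", "unlabeled", "validation"):
            g = f[name]
            pools[name] = Pool(
                images=np.asarray(g["images"]),
                masks=np.asarray(g["masks"]) if "masks" in g else None,
                indices=np.asarray(g["indices"]),
                hidden_masks=(np.asarray(g["hidden_masks"])
                              if "hidden_masks" in g else None),
            )
    return Dataset(labeled=pools["labeled"], unlabeled=pools["unlabeled"],
                   validation=pools["validation"], spec=spec)
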