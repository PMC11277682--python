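"""Image preparation: resize, dataset-level standardization, geometric
augmentation, and the train/validation split.

Preparation is deterministic (resize to the model grid, standardize with
statistics pooled over the *training* images only); augmentation is
stochastic and geometric only — random horizontal/vertical flips, rotation
in ±0.2 rad, and shifts of up to ±20% of each dimension — with the same
sampled transform applied to the image (bilinear) and both mask channels
(nearest neighbour) so pairs stay aligned.

The CTR is a ratio of horizontal widths, so the resize is a direct
anisotropic mapping to the model grid with no letterboxing: axis-aligned
scaling leaves the ratio unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .core import SegmentationMask

__all__ = [
    "NormStats",
    "AugmentConfig",
    "SplitSpec",
    "DegenerateVarianceError",
    "resize_to_model",
    "fit_normalizer",
    "standardize",
    "augment",
    "split_dataset",
]


class DegenerateVarianceError(ValueError):
    """Pooled training pixels are constant; standardization undefined."""


@dataclass(frozen=True)
class NormStats:
    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise ValueError("std must be strictly positive")


@dataclass(frozen=True)
class AugmentConfig:
    p_flip_horizontal: float = 0.5
    p_flip_vertical: float = 0.5
    max_rotation: float = 0.2       # radians
    max_shift_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_flip_horizontal <= 1 and 0 <= self.p_flip_vertical <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.max_rotation < 0 or not (0 <= self.max_shift_fraction < 1):
            raise ValueError("invalid rotation/shift bounds")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def resize_to_model(img: np.ndarray, target: tuple = (256, 256),
                    is_mask: bool = False) -> np.ndarray:
    """Resize to the model grid: bilinear for images, nearest for masks."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("input must be a 2-D matrix of size >= 2x2")
    if not np.isfinite(img).all():
        raise ValueError("input contains non-finite values")
    if img.shape == tuple(target):
        return img.copy()
    if is_mask:
        out = _sk_resize(img, target, order=0, preserve_range=True,
                         anti_aliasing=False)
        return (out > 0.5).astype(img.dtype) if _is_binary(img) else out
    return _sk_resize(img, target, order=1, preserve_range=True)


def _is_binary(arr: np.ndarray) -> bool:
    return bool(np.isin(np.unique(arr), (0, 1)).all())


def fit_normalizer(train_images) -> NormStats:
    """Pooled pixel mean and standard deviation over the training images."""
    arrs = [np.asarray(im, dtype=np.float64).ravel() for im in train_images]
    if not arrs:
        raise ValueError("at least one training image required")
    pooled = np.concatenate(arrs)
    mean = float(pooled.mean())
    std = float(pooled.std())
    if std == 0:
        raise DegenerateVarianceError("training pixels are constant")
    return NormStats(mean=mean, std=std)


def standardize(img: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(img, dtype=np.float64) - stats.mean) / stats.std


def _affine_params(shape, cfg: AugmentConfig, rng: np.random.Generator):
    flip_h = rng.random() < cfg.p_flip_horizontal
    flip_v = rng.random() < cfg.p_flip_vertical
    theta = float(rng.uniform(-cfg.max_rotation, cfg.max_rotation)) \
        if cfg.max_rotation > 0 else 0.0
    f = cfg.max_shift_fraction
    if f > 0:
        dr = float(rng.uniform(-f, f)) * shape[0]
        dc = float(rng.uniform(-f, f)) * shape[1]
    else:
        dr = dc = 0.0
    return flip_h, flip_v, theta, (dr, dc)


def _apply_geometric(arr, flip_h, flip_v, theta, shift, order):
    out = arr
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if theta != 0.0 or shift != (0.0, 0.0):
        # forward map: rotate about the center by theta, then translate;
        # ndimage wants the inverse map output -> input
        c = (np.array(out.shape) - 1) / 2.0
        cos, sin = math.cos(theta), math.sin(theta)
        rot_inv = np.array([[cos, sin], [-sin, cos]])
        offset = c - rot_inv @ (c + np.asarray(shift))
        out = ndimage.affine_transform(np.asarray(out, dtype=np.float64),
                                       rot_inv, offset=offset, order=order,
                                       mode="constant", cval=0.0)
    return np.ascontiguousarray(out)


def augment(img: np.ndarray, mask: SegmentationMask, cfg: AugmentConfig,
            rng: np.random.Generator) -> tuple:
    """One random geometric transform applied identically to image and mask.

    With all probabilities and bounds at zero this is a bit-exact identity.
    Out-of-canvas regions are filled with 0 (background-neutral after
    standardization); mask channels use nearest-neighbour interpolation and
    stay binary.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    flip_h, flip_v, theta, shift = _affine_params(img.shape, cfg, rng)
    out_img = _apply_geometric(img, flip_h, flip_v, theta, shift, order=1)
    heart = _apply_geometric(mask.heart, flip_h, flip_v, theta, shift, order=0)
    lungs = _apply_geometric(mask.lungs, flip_h, flip_v, theta, shift, order=0)
    out_mask = SegmentationMask(heart=(heart > 0.5).astype(np.uint8),
                                lungs=(lungs > 0.5).astype(np.uint8))
    return out_img, out_mask


def split_dataset(ids, spec: SplitSpec | None = None) -> tuple:
    """Seeded shuffle split: |train| = floor(train_fraction · n).

    Floor rounding reproduces the 847/212 partition of 1059 annotated
    images at the default 80% fraction.
    """
    spec = spec or SplitSpec()
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(math.floor(spec.train_fraction * n))
    train_ids = [ids[i] for i in order[:n_train]]
    val_ids = [ids[i] for i in order[n_train:]]
    return train_ids, val_ids
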