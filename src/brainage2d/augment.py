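"""Offline augmentation of packed projection images.

The training split is expanded with randomly perturbed copies: a small
affine perturbation (scale, shear, rotation composed about the image
center) followed by an elastic deformation (Gaussian-smoothed random
displacement field). Augmentation is offline — copies are materialized
once and concatenated with the originals — and train-only; the age
labels are copied unchanged.

All channels of one plane of one pseudo-subject share a single geometric
transform, because the mean and std images of a plane are views of the
same anatomy and must deform together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projection import PLANES, PackedDataset, SplitArrays


@dataclass(frozen=True)
class AugmentationConfig:
    n_copies: int = 3
    scale_range: tuple[float, float] = (0.95, 1.05)
    shear_deg: float = 5.0
    rotation_deg: float = 5.0
    elastic_alpha: float = 2.0
    elastic_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        lo, hi = self.scale_range
        if not (lo <= 1.0 <= hi):
            raise ValueError("scale_range must bracket 1.0")
        if min(self.shear_deg, self.rotation_deg, self.elastic_alpha,
               self.elastic_sigma) < 0:
            raise ValueError("perturbation magnitudes must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.scale_range == (1.0, 1.0) and self.shear_deg == 0.0
                and self.rotation_deg == 0.0 and self.elastic_alpha == 0.0)


def _draw_transform(config: AugmentationConfig, rng: np.random.Generator, shape):
    scale = rng.uniform(*config.scale_range)
    shear = np.deg2rad(rng.uniform(-config.shear_deg, config.shear_deg))
    theta = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shm = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    mat = rot @ shm @ (np.eye(2) * scale)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    # ndimage.affine_transform maps output coords to input: use the inverse
    inv = np.linalg.inv(mat)
    offset = center - inv @ center
    disp = None
    if config.elastic_alpha > 0:
        fields = rng.uniform(-1.0, 1.0, size=(2, *shape))
        disp = np.stack([
            ndimage.gaussian_filter(f, config.elastic_sigma, mode="constant")
            for f in fields
        ])
        norm = np.abs(disp).max()
        if norm > 0:
            disp *= config.elastic_alpha / norm
    return inv, offset, disp


def _apply_transform(img: np.ndarray, inv, offset, disp) -> np.ndarray:
    out = ndimage.affine_transform(img, inv, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    if disp is not None:
        grid = np.indices(img.shape, dtype=np.float64)
        coords = grid + disp
        out = ndimage.map_coordinates(out, coords, order=1,
                                      mode="constant", cval=0.0)
    return out.astype(np.float32)


def augment_image(img: np.ndarray, config: AugmentationConfig, draw_seed: int) -> np.ndarray:
    """Perturb one 2D image; deterministic given ``draw_seed``."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"augment_image expects a 2D image, got {img.ndim}D")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if config.is_identity:
        return img.astype(np.float32).copy()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, int(draw_seed))))
    inv, offset, disp = _draw_transform(config, rng, img.shape)
    return _apply_transform(img, inv, offset, disp)


def build_augmented_set(dataset: PackedDataset, config: AugmentationConfig,
                        split: str = "train") -> SplitArrays:
    """Expand the training split to (1 + n_copies) x its size.

    Copies are perturbed independently per (copy, subject, plane); all
    channels of a plane share the transform. Returns a new
    :class:`SplitArrays` (originals first, then copy 1, copy 2, ...);
    augmenting the validation or test split is refused.
    """
    if split != "train":
        raise ValueError("augmentation is train-only; refusing to augment "
                         f"split {split!r}")
    sp = dataset.splits[split]
    if config.n_copies == 0:
        return SplitArrays({p: a.copy() for p, a in sp.planes.items()},
                           sp.ages.copy(), list(sp.subject_ids))

    plane_index = {p: i for i, p in enumerate(PLANES)}
    out_planes = {p: [a] for p, a in sp.planes.items()}
    ids = list(sp.subject_ids)
    for copy_i in range(1, config.n_copies + 1):
        for p, arr in sp.planes.items():
            n, c, h, w = arr.shape
            new = np.empty_like(arr)
            for si in range(n):
                if config.is_identity:
                    new[si] = arr[si]
                    continue
                rng = np.random.default_rng(np.random.SeedSequence(
                    (config.seed, copy_i, si, plane_index[p])))
                inv, offset, disp = _draw_transform(config, rng, (h, w))
                for ci in range(c):
                    new[si, ci] = _apply_transform(arr[si, ci], inv, offset, disp)
            out_planes[p].append(new)
        ids.extend(f"{sid}_aug{copy_i}" for sid in sp.subject_ids)
    planes = {p: np.concatenate(stacks) for p, stacks in out_planes.items()}
    ages = np.tile(sp.ages, config.n_copies + 1)
    return SplitArrays(planes, ages, ids)
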