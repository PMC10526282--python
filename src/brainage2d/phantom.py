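"""Aging-brain phantom generator.

Produces ellipsoid-based gray-matter-likelihood volumes whose morphology
changes deterministically with age: an outer cortical shell that thins
linearly and a central ventricle that grows linearly. The phantoms make
every downstream stage (padding, projection, augmentation, training,
ablation) testable at desk scale with a known age signal; they do not
attempt anatomical realism (no folding, no tissue classes beyond a
shell/interior/ventricle partition, no scanner artifacts).

Intensity layout (before smoothing and noise):
outside 0.0, interior (white-matter-like) 0.25, cortical shell 0.9,
ventricle 0.02. All values live in [0, 1] like a segmentation likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_io import BrainVolume, save_volume

SHELL_VALUE = 0.9
INTERIOR_VALUE = 0.25
VENTRICLE_VALUE = 0.02
#: reference age at which shell thickness / ventricle radius are specified
REFERENCE_AGE = 44

SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters of the phantom cohort.

    Lengths are in voxels of the configured grid; rates are voxels per
    year of age. The defaults describe a quarter-linear-scale grid
    (64 x 64 x 52) of the full 256 x 256 x 208 acquisition matrix.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 52)
    age_range: tuple[int, int] = (44, 82)
    shell_thickness_at_44: float = 5.0
    thinning_rate: float = 0.08
    ventricle_radius_at_44: float = 4.0
    ventricle_growth_rate: float = 0.05
    subject_variability: float = 0.03
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        gs = tuple(int(s) for s in self.grid_shape)
        object.__setattr__(self, "grid_shape", gs)
        if len(gs) != 3 or any(s < 16 for s in gs):
            raise ValueError(f"grid_shape dimensions must each be >= 16, got {gs}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        if self.thinning_rate <= 0:
            raise ValueError("thinning_rate must be > 0")
        if self.ventricle_growth_rate < 0:
            raise ValueError("ventricle_growth_rate must be >= 0")
        if self.thinning_rate * (hi - lo) >= self.shell_thickness_at_44:
            raise ValueError(
                "shell would vanish within the age range: need "
                "thinning_rate * (age_max - age_min) < shell_thickness_at_44"
            )


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic description of one subject's phantom at one age."""

    brain_axes: tuple[float, float, float]
    shell_thickness: float
    ventricle_axes: tuple[float, float, float]
    center: tuple[float, float, float]


def _subject_rng(params: PhantomParams, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((params.seed, int(subject_seed))))


def phantom_geometry(params: PhantomParams, age: float, subject_seed: int) -> PhantomGeometry:
    """Morphology of the phantom; jitter depends on the subject, not the age."""
    lo, hi = params.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside the configured range [{lo}, {hi}]")
    rng = _subject_rng(params, subject_seed)
    jitter_brain = rng.normal(0.0, params.subject_variability, size=3)
    jitter_vent = rng.normal(0.0, params.subject_variability, size=3)
    gx, gy, gz = params.grid_shape
    brain = np.array([0.42 * gx, 0.42 * gy, 0.42 * gz]) * (1.0 + jitter_brain)
    t = params.shell_thickness_at_44 - params.thinning_rate * (age - REFERENCE_AGE)
    rv = params.ventricle_radius_at_44 + params.ventricle_growth_rate * (age - REFERENCE_AGE)
    vent = rv * np.array([1.0, 0.6, 0.8]) * (1.0 + jitter_vent)
    center = ((gx - 1) / 2.0, (gy - 1) / 2.0, (gz - 1) / 2.0)
    return PhantomGeometry(tuple(brain), float(t), tuple(vent), center)


def _ellipsoid_rho(shape, center, axes) -> np.ndarray:
    coords = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    rho2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, axes))
    return np.sqrt(rho2)


def generate_phantom(params: PhantomParams, age: float, subject_seed: int) -> BrainVolume:
    """Generate one phantom volume; deterministic in (params, age, subject_seed).

    The cortical shell occupies normalized radii [1 - t/a_mean, 1] of the
    brain ellipsoid, so with jitter fixed the shell region shrinks with
    age by set inclusion and the ventricle region grows by set inclusion;
    both voxel-count trends are therefore monotone before noise.
    """
    geom = phantom_geometry(params, age, subject_seed)
    shape = params.grid_shape
    rho_brain = _ellipsoid_rho(shape, geom.center, geom.brain_axes)
    a_mean = float(np.mean(geom.brain_axes))
    rho_inner = 1.0 - geom.shell_thickness / a_mean
    rho_vent = _ellipsoid_rho(shape, geom.center, geom.ventricle_axes)

    vol = np.zeros(shape, dtype=np.float32)
    vol[rho_brain <= 1.0] = INTERIOR_VALUE
    vol[(rho_brain <= 1.0) & (rho_brain >= rho_inner)] = SHELL_VALUE
    vol[rho_vent <= 1.0] = VENTRICLE_VALUE
    vol = gaussian_filter(vol, sigma=0.5).astype(np.float32)

    if params.noise_sigma > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence((params.seed, int(subject_seed), int(round(age))))
        )
        vol = vol + noise_rng.normal(0.0, params.noise_sigma, size=shape).astype(np.float32)
    return BrainVolume(np.clip(vol, 0.0, 1.0), age=int(round(age)))


def gray_matter_count(vol: BrainVolume, threshold: float = 0.5) -> int:
    """Voxels above the gray-matter likelihood threshold."""
    return int(np.count_nonzero(vol.data > threshold))


def ventricle_count(params: PhantomParams, vol: BrainVolume, age: float,
                    subject_seed: int, threshold: float = 0.1) -> int:
    """Low-intensity voxels inside the analytic brain interior."""
    geom = phantom_geometry(params, age, subject_seed)
    rho = _ellipsoid_rho(params.grid_shape, geom.center, geom.brain_axes)
    a_mean = float(np.mean(geom.brain_axes))
    interior = rho < (1.0 - geom.shell_thickness / a_mean)
    return int(np.count_nonzero(interior & (vol.data < threshold)))


@dataclass
class Cohort:
    """An ordered collection of phantom subjects with a train/val/test split."""

    params: PhantomParams
    subject_ids: list[str]
    ages: np.ndarray
    volumes: list[BrainVolume]
    split: list[str]

    def __post_init__(self):
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subject_ids)

    def manifest(self, paths: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "subject_id": self.subject_ids,
            "age": np.asarray(self.ages, dtype=int),
            "split": self.split,
        })
        if paths is not None:
            df["path"] = paths
        return df


def split_sizes(n: int) -> tuple[int, int, int]:
    """70/15/15 split with the test set absorbing the rounding remainder."""
    n_train = int(np.floor(0.7 * n))
    n_val = int(np.floor(0.15 * n))
    return n_train, n_val, n - n_train - n_val


def sample_ages(params: PhantomParams, n: int) -> np.ndarray:
    """Uniform integer ages over the configured range (1-year resolution)."""
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xC0)))
    lo, hi = params.age_range
    return rng.integers(lo, hi + 1, size=n)


def generate_cohort(params: PhantomParams, n: int,
                    ages: list[int] | None = None) -> Cohort:
    """Generate ``n`` phantom subjects with uniform integer ages.

    The split is assigned deterministically from ``params.seed`` by
    shuffling subject order and cutting at the 70/15/15 boundaries.
    """
    if n < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    n_train, n_val, n_test = split_sizes(n)
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"n={n} cannot fill all three splits "
            f"(train/val/test = {n_train}/{n_val}/{n_test})"
        )
    if ages is None:
        age_arr = sample_ages(params, n)
    else:
        if len(ages) != n:
            raise ValueError(f"got {len(ages)} ages for n={n}")
        age_arr = np.asarray(ages, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xC1)))
    order = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_val]] = "val"
    split[order[n_train + n_val:]] = "test"

    ids, volumes = [], []
    for i in range(n):
        ids.append(f"sub-{i:05d}")
        volumes.append(generate_phantom(params, int(age_arr[i]), subject_seed=i))
    return Cohort(params, ids, age_arr, volumes, list(split))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write volumes as .nii.gz plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, age, vol in zip(cohort.subject_ids, cohort.ages, cohort.volumes):
        p = out_dir / f"{sid}.nii.gz"
        save_volume(BrainVolume(vol.data, subject_id=sid, age=int(age)), p)
        paths.append(p.name)
    manifest_path = out_dir / "manifest.csv"
    cohort.manifest(paths).to_csv(manifest_path, index=False)
    return manifest_path
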