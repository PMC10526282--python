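"""Reading, writing and grid-padding of 3D brain volumes.

The canonical in-memory axis convention is RAS-like:
axis 0 = left-right (sagittal index), axis 1 = posterior-anterior
(coronal index), axis 2 = inferior-superior (axial index). Volumes loaded
from NIfTI are reoriented to this convention using the stored affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: default full-resolution common grid (the reference acquisition matrix)
FULL_GRID = (256, 256, 208)


@dataclass
class BrainVolume:
    """A 3D scalar volume with optional subject metadata.

    ``data`` holds intensities (gray-matter likelihood or raw T1) as
    float32; ``age`` is in integer years when known.
    """

    data: np.ndarray
    subject_id: str = ""
    age: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(
                f"BrainVolume requires 3D data, got {self.data.ndim}D "
                f"with shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass(frozen=True)
class GridSpec:
    """Common target grid every volume is padded to."""

    target_shape: tuple[int, int, int] = FULL_GRID

    def __post_init__(self):
        if len(self.target_shape) != 3 or any(int(s) < 1 for s in self.target_shape):
            raise ValueError(f"invalid target shape {self.target_shape}")
        object.__setattr__(self, "target_shape", tuple(int(s) for s in self.target_shape))


def load_volume(path: str | Path, *, subject_id: str = "", age: int | None = None) -> BrainVolume:
    """Load a NIfTI file and reorient it to the canonical axis convention.

    Raises ``ValueError`` for non-3D images or non-finite content and
    ``FileNotFoundError`` for missing files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D volume, {path.name} is {img.ndim}D")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if not np.isfinite(data).all():
        raise ValueError(f"volume {path.name} contains NaN or Inf values")
    return BrainVolume(data, subject_id=subject_id or path.stem.replace(".nii", ""), age=age)


def save_volume(vol: BrainVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with an identity (RAS) affine.

    gzip members are written with a zeroed mtime so that identical
    volumes produce byte-identical ``.nii.gz`` files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=np.eye(4))
    img.to_filename(str(path))
    return path


def pad_to_grid(vol: BrainVolume, grid: GridSpec) -> BrainVolume:
    """Zero-pad symmetrically to the target grid, centring the volume.

    When a margin is odd the extra voxel goes to the high-index side.
    """
    target = grid.target_shape
    margins = []
    for s, t in zip(vol.shape, target):
        if s > t:
            raise ValueError(
                f"volume shape {vol.shape} exceeds target grid {target}"
            )
        before = (t - s) // 2
        margins.append((before, t - s - before))
    if all(m == (0, 0) for m in margins):
        return vol
    data = np.pad(vol.data, margins, mode="constant", constant_values=0.0)
    return BrainVolume(data, subject_id=vol.subject_id, age=vol.age)
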