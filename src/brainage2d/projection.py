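"""Moment projections: collapse a 3D volume into per-plane 2D images.

Each channel is identified by a plane (the anatomical slicing direction
whose normal axis is reduced) and a statistic. On the canonical axis
convention the reductions are::

    axial     reduce axis 2 (inferior-superior)  -> image (axis0, axis1)
    coronal   reduce axis 1 (posterior-anterior) -> image (axis0, axis2)
    sagittal  reduce axis 0 (left-right)         -> image (axis1, axis2)

so a 256 x 256 x 208 volume yields a 256 x 256 axial image and
256 x 208 coronal/sagittal images. Statistics are computed over the full
padded extent (all-zero slices included): mean, population standard
deviation, and optionally the standardized third and fourth central
moments (skew, kurtosis; defined as 0 where the std is 0).
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import BrainVolume, GridSpec, load_volume, pad_to_grid

PLANES = ("axial", "coronal", "sagittal")
STATISTICS = ("mean", "std", "skew", "kurtosis")
PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}


@dataclass(frozen=True, order=True)
class ChannelTag:
    """One projection channel: a plane crossed with a statistic."""

    plane: str
    statistic: str

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")
        if self.statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}"
            )

    def __str__(self) -> str:
        return f"{self.plane}-{self.statistic}"

    @classmethod
    def parse(cls, token: str) -> "ChannelTag":
        try:
            plane, statistic = token.split("-", 1)
        except ValueError:
            raise ValueError(f"cannot parse channel tag {token!r}") from None
        return cls(plane, statistic)


def canonical_order(channels) -> tuple[ChannelTag, ...]:
    """Fixed channel ordering: planes (axial, coronal, sagittal) x statistics."""
    chans = set(channels)
    out = [ChannelTag(p, s) for p in PLANES for s in STATISTICS if ChannelTag(p, s) in chans]
    if len(out) != len(chans):
        raise ValueError("duplicate or unknown channels")
    return tuple(out)


#: the six standard channels: mean and std per plane
DEFAULT_CHANNELS = tuple(ChannelTag(p, s) for p in PLANES for s in ("mean", "std"))
MEAN_CHANNELS = tuple(ChannelTag(p, "mean") for p in PLANES)
STD_CHANNELS = tuple(ChannelTag(p, "std") for p in PLANES)


@dataclass
class ProjectionSet:
    """The tagged 2D images of one subject."""

    subject_id: str
    age: int | None
    images: dict[ChannelTag, np.ndarray]


def _moments(data: np.ndarray, axis: int, stats: set[str]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    mean = data.mean(axis=axis)
    if "mean" in stats:
        out["mean"] = mean.astype(np.float32)
    need_higher = stats & {"std", "skew", "kurtosis"}
    if need_higher:
        centered = data - np.expand_dims(mean, axis)
        var = np.mean(centered ** 2, axis=axis)
        std = np.sqrt(var)
        if "std" in stats:
            out["std"] = std.astype(np.float32)
        if "skew" in stats or "kurtosis" in stats:
            safe = np.where(std > 0, std, 1.0)
            if "skew" in stats:
                m3 = np.mean(centered ** 3, axis=axis)
                out["skew"] = np.where(std > 0, m3 / safe ** 3, 0.0).astype(np.float32)
            if "kurtosis" in stats:
                m4 = np.mean(centered ** 4, axis=axis)
                out["kurtosis"] = np.where(std > 0, m4 / safe ** 4, 0.0).astype(np.float32)
    return out


def project(vol: BrainVolume, channels=DEFAULT_CHANNELS) -> ProjectionSet:
    """Project a volume into the requested moment images."""
    channels = canonical_order(channels)
    if not channels:
        raise ValueError("empty channel set")
    data = vol.data.astype(np.float64)
    images: dict[ChannelTag, np.ndarray] = {}
    for plane in PLANES:
        stats = {c.statistic for c in channels if c.plane == plane}
        if not stats:
            continue
        res = _moments(data, PLANE_AXIS[plane], stats)
        for stat, img in res.items():
            images[ChannelTag(plane, stat)] = img
    return ProjectionSet(vol.subject_id, vol.age, {c: images[c] for c in channels})


@dataclass
class SplitArrays:
    """Per-split packed arrays: one (N, C, H, W) array per plane."""

    planes: dict[str, np.ndarray]
    ages: np.ndarray
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.subject_ids)


@dataclass
class PackedDataset:
    """Whole-cohort projections, resident in memory.

    Per-plane arrays are kept separate because the plane image shapes
    differ. Channel ordering within a plane follows ``channels``.
    """

    channels: tuple[ChannelTag, ...]
    grid: tuple[int, int, int]
    splits: dict[str, SplitArrays]
    manifest_hash: str = ""

    @property
    def plane_names(self) -> tuple[str, ...]:
        return tuple(p for p in PLANES if any(c.plane == p for c in self.channels))

    def plane_channels(self, plane: str) -> tuple[ChannelTag, ...]:
        return tuple(c for c in self.channels if c.plane == plane)

    def subset(self, channels) -> "PackedDataset":
        """Restrict to a channel subset without re-projecting."""
        channels = canonical_order(channels)
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise ValueError(f"channels not in dataset: {[str(c) for c in missing]}")
        splits = {}
        for name, sp in self.splits.items():
            planes = {}
            for plane in PLANES:
                idx = [i for i, c in enumerate(self.plane_channels(plane))
                       if c in channels]
                if idx:
                    planes[plane] = sp.planes[plane][:, idx]
            splits[name] = SplitArrays(planes, sp.ages, list(sp.subject_ids))
        return PackedDataset(channels, self.grid, splits, self.manifest_hash)


def _image_shape(grid, plane) -> tuple[int, int]:
    gx, gy, gz = grid
    return {"axial": (gx, gy), "coronal": (gx, gz), "sagittal": (gy, gz)}[plane]


def pack_from_volumes(volumes, subject_ids, ages, split_labels, channels=DEFAULT_CHANNELS,
                      grid: GridSpec | None = None, manifest_hash: str = "") -> PackedDataset:
    """Pad, project and pack volumes, preserving the given subject order."""
    channels = canonical_order(channels)
    if not channels:
        raise ValueError("empty channel set")
    if grid is None:
        shapes = np.array([v.shape for v in volumes])
        grid = GridSpec(tuple(int(s) for s in shapes.max(axis=0)))
    bad = [sid for sid, v in zip(subject_ids, volumes)
           if any(s > t for s, t in zip(v.shape, grid.target_shape))]
    if bad:
        raise ValueError(f"volumes exceed the target grid: {bad}")

    per_split: dict[str, list[int]] = {}
    for i, lab in enumerate(split_labels):
        per_split.setdefault(lab, []).append(i)

    planes_in_use = tuple(p for p in PLANES if any(c.plane == p for c in channels))
    splits = {}
    for name, idxs in per_split.items():
        plane_stacks: dict[str, list[np.ndarray]] = {p: [] for p in planes_in_use}
        for i in idxs:
            pv = pad_to_grid(volumes[i], grid)
            ps = project(pv, channels)
            for p in planes_in_use:
                chans = [ps.images[c] for c in channels if c.plane == p]
                plane_stacks[p].append(np.stack(chans))
        splits[name] = SplitArrays(
            {p: np.stack(v).astype(np.float32) for p, v in plane_stacks.items()},
            np.asarray([ages[i] for i in idxs], dtype=np.float32),
            [subject_ids[i] for i in idxs],
        )
    return PackedDataset(channels, grid.target_shape, splits, manifest_hash)


def pack_cohort(cohort, channels=DEFAULT_CHANNELS, grid: GridSpec | None = None) -> PackedDataset:
    """Pack an in-memory phantom cohort."""
    if grid is None:
        grid = GridSpec(cohort.params.grid_shape)
    return pack_from_volumes(cohort.volumes, cohort.subject_ids,
                             np.asarray(cohort.ages, dtype=float), cohort.split,
                             channels=channels, grid=grid)


def pack_dataset(manifest_path: str | Path, channels=DEFAULT_CHANNELS,
                 grid: GridSpec | None = None, out_path: str | Path | None = None
                 ) -> PackedDataset:
    """Pack a cohort from a manifest CSV (subject_id, age, split, path)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "age", "split", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    volumes = [load_volume(manifest_path.parent / p) for p in df["path"]]
    mhash = hashlib.sha256(manifest_path.read_bytes()).hexdigest()
    ds = pack_from_volumes(volumes, list(df["subject_id"]), df["age"].to_numpy(float),
                           list(df["split"]), channels=channels, grid=grid,
                           manifest_hash=mhash)
    if out_path is not None:
        save_packed(ds, out_path)
    return ds


def save_packed(ds: PackedDataset, path: str | Path) -> Path:
    """Serialize to an uncompressed .npz with embedded JSON metadata.

    Written with fixed zip timestamps, so identical datasets produce
    byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "channels": [str(c) for c in ds.channels],
        "grid": list(ds.grid),
        "splits": {},
        "manifest_hash": ds.manifest_hash,
    }
    arrays: dict[str, np.ndarray] = {}
    for name, sp in sorted(ds.splits.items()):
        meta["splits"][name] = {"subject_ids": list(sp.subject_ids),
                                "planes": sorted(sp.planes)}
        arrays[f"{name}__ages"] = np.asarray(sp.ages, dtype=np.float32)
        for plane, arr in sorted(sp.planes.items()):
            arrays[f"{name}__{plane}"] = arr
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo("metadata.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, json.dumps(meta, sort_keys=True))
        for key in sorted(arrays):
            abuf = io.BytesIO()
            np.save(abuf, arrays[key])
            info = zipfile.ZipInfo(f"{key}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, abuf.getvalue())
    path.write_bytes(buf.getvalue())
    return path


def load_packed(path: str | Path) -> PackedDataset:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("metadata.json"))
        splits = {}
        for name, info in meta["splits"].items():
            ages = np.load(io.BytesIO(zf.read(f"{name}__ages.npy")))
            planes = {p: np.load(io.BytesIO(zf.read(f"{name}__{p}.npy")))
                      for p in info["planes"]}
            splits[name] = SplitArrays(planes, ages, list(info["subject_ids"]))
    channels = tuple(ChannelTag.parse(c) for c in meta["channels"])
    return PackedDataset(channels, tuple(meta["grid"]), splits, meta.get("manifest_hash", ""))


def export_projection_png(ps: ProjectionSet, path: str | Path) -> Path:
    """Save a montage of the projection images for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tags = list(ps.images)
    fig, axes = plt.subplots(1, len(tags), figsize=(3 * len(tags), 3))
    if len(tags) == 1:
        axes = [axes]
    for ax, tag in zip(axes, tags):
        ax.imshow(ps.images[tag].T, origin="lower", cmap="gray")
        ax.set_title(str(tag), fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
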