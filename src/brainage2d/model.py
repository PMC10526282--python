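"""Three-stream 2D convolutional regression networks.

One convolutional stack per anatomical plane maps that plane's
projection channels to a 256w-dimensional feature vector (w = width
multiplier); the three feature vectors are concatenated and fed through
a dense head ending in a single linear output node (the predicted age in
years). With ``iso=True`` the three stacks share one set of weights.

Architecture of one stack (width multiplier w, d convolutions per block):

    6 blocks, filters 4w, 8w, 16w, 32w, 64w, 128w:
        Conv3x3(bias) + ReLU                    (block entry)
        [Conv3x3(bias) + ReLU] x (d - 2)        (depth 19 adds 1, depth 25 adds 2)
        Conv3x3(no bias) + BatchNorm + ReLU [+ Dropout 0.2]
        MaxPool 2x2 (ceil)
    final Conv3x3(128w -> 256w, bias) + ReLU
    global mean pool -> 256w features

Depths 13/19/25 correspond to 2/3/4 convolutions per block (batch
normalization lands after every 2nd/3rd/4th convolution) plus the final
convolution. The dense head is

    concat(256w x planes) -> 160w -> 128w -> 672w -> 10 -> 1

with ReLU between layers and a linear output. The head dimensions were
solved from the published trainable-parameter counts of the printed
architecture report, which pin them uniquely together with the stack
layout; see docs/methods.md for the derivation.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .projection import DEFAULT_CHANNELS, PLANES, ChannelTag, canonical_order

SUPPORTED_DEPTHS = (13, 19, 25)
SUPPORTED_WIDTHS = (0.5, 1.0, 2.0)
#: base filter progression of the six blocks (before width scaling)
BLOCK_FILTERS = (4, 8, 16, 32, 64, 128)
FINAL_FILTERS = 256
#: dense head hidden sizes; the first three scale with width
HEAD_SCALED = (160, 128, 672)
HEAD_FIXED = 10


@dataclass(frozen=True)
class ModelSpec:
    """Architecture configuration."""

    depth: int = 13
    width: float = 1.0
    channels: tuple[ChannelTag, ...] = DEFAULT_CHANNELS
    iso: bool = False
    dropout_placement: str = "between_conv"
    dropout_rate_conv: float = 0.2
    dropout_rate_dense: float = 0.3
    features_per_stack: int = FINAL_FILTERS

    def __post_init__(self):
        if self.depth not in SUPPORTED_DEPTHS:
            raise ValueError(f"unsupported depth {self.depth}; choose from {SUPPORTED_DEPTHS}")
        if float(self.width) not in SUPPORTED_WIDTHS:
            raise ValueError(f"unsupported width {self.width}; choose from {SUPPORTED_WIDTHS}")
        if self.dropout_placement not in ("between_conv", "between_dense"):
            raise ValueError(f"unknown dropout placement {self.dropout_placement!r}")
        object.__setattr__(self, "channels", canonical_order(self.channels))
        if not self.channels:
            raise ValueError("at least one channel must be selected")
        if self.iso:
            counts = {len(self.plane_channels(p)) for p in self.planes}
            if len(counts) > 1:
                raise ValueError("iso weight sharing requires equal channel counts per plane")

    @property
    def planes(self) -> tuple[str, ...]:
        return tuple(p for p in PLANES if any(c.plane == p for c in self.channels))

    def plane_channels(self, plane: str) -> tuple[ChannelTag, ...]:
        return tuple(c for c in self.channels if c.plane == plane)

    @property
    def convs_per_block(self) -> int:
        return {13: 2, 19: 3, 25: 4}[self.depth]

    def scaled(self, base: int) -> int:
        return int(round(base * float(self.width)))

    def to_json(self) -> str:
        d = {
            "depth": self.depth, "width": float(self.width),
            "channels": [str(c) for c in self.channels], "iso": self.iso,
            "dropout_placement": self.dropout_placement,
            "dropout_rate_conv": self.dropout_rate_conv,
            "dropout_rate_dense": self.dropout_rate_dense,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["channels"] = tuple(ChannelTag.parse(c) for c in d["channels"])
        return cls(**d)


def _build_stack(spec: ModelSpec, c_in: int, rng: np.random.Generator,
                 name: str) -> nn.Sequential:
    layers: list[nn.Layer] = []
    prev = c_in
    d = spec.convs_per_block
    for bi, base_f in enumerate(BLOCK_FILTERS):
        f = spec.scaled(base_f)
        layers += [nn.Conv2D(prev, f, rng=rng, name=f"{name}.block{bi}.conv0"), nn.ReLU()]
        for j in range(1, d - 1):
            layers += [nn.Conv2D(f, f, rng=rng, name=f"{name}.block{bi}.conv{j}"), nn.ReLU()]
        layers += [
            nn.Conv2D(f, f, bias=False, rng=rng, name=f"{name}.block{bi}.conv{d - 1}"),
            nn.BatchNorm2d(f, name=f"{name}.block{bi}.bn"),
            nn.ReLU(),
        ]
        if spec.dropout_placement == "between_conv":
            layers.append(nn.Dropout(spec.dropout_rate_conv))
        layers.append(nn.MaxPool2())
        prev = f
    layers += [
        nn.Conv2D(prev, spec.scaled(FINAL_FILTERS), rng=rng, name=f"{name}.final"),
        nn.ReLU(),
        nn.GlobalMeanPool(),
    ]
    return nn.Sequential(layers)


def _build_head(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    d_in = spec.scaled(FINAL_FILTERS) * len(spec.planes)
    dims = [spec.scaled(h) for h in HEAD_SCALED] + [HEAD_FIXED]
    layers: list[nn.Layer] = []
    prev = d_in
    for i, h in enumerate(dims):
        layers += [nn.Dense(prev, h, rng=rng, name=f"head.dense{i}"), nn.ReLU()]
        if spec.dropout_placement == "between_dense" and i < 2:
            layers.append(nn.Dropout(spec.dropout_rate_dense))
        prev = h
    layers.append(nn.Dense(prev, 1, rng=rng, name="head.out"))
    return nn.Sequential(layers)


class ProjectionNet:
    """The assembled multi-stream network."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA5C)))
        self.stacks: dict[str, nn.Sequential] = {}
        if spec.iso:
            c_in = len(spec.plane_channels(spec.planes[0]))
            shared = _build_stack(spec, c_in, rng, "stack")
            for p in spec.planes:
                self.stacks[p] = shared
        else:
            for p in spec.planes:
                c_in = len(spec.plane_channels(p))
                self.stacks[p] = _build_stack(spec, c_in, rng, f"stack.{p}")
        self.head = _build_head(spec, rng)

    # -- parameters ----------------------------------------------------
    def params(self) -> list[nn.Param]:
        """Unique trainable parameters (shared stacks counted once)."""
        out: dict[int, nn.Param] = {}
        for p in self.spec.planes:
            for par in self.stacks[p].params():
                out.setdefault(id(par), par)
        for par in self.head.params():
            out.setdefault(id(par), par)
        return list(out.values())

    # -- forward / backward --------------------------------------------
    def _check_batch(self, batch: dict[str, np.ndarray]) -> None:
        for p in self.spec.planes:
            if p not in batch:
                raise ValueError(f"batch missing plane {p!r}")
            c_expected = len(self.spec.plane_channels(p))
            if batch[p].shape[1] != c_expected:
                raise ValueError(
                    f"plane {p!r}: expected {c_expected} channels, got {batch[p].shape[1]}"
                )

    def forward(self, batch: dict[str, np.ndarray], *, training: bool = False,
                rng: np.random.Generator | None = None):
        self._check_batch(batch)
        feats, caches = [], []
        for p in self.spec.planes:
            # packed arrays are (N, C, H, W); the engine runs channels-last
            nhwc = np.ascontiguousarray(
                batch[p].astype(np.float32).transpose(0, 2, 3, 1))
            f, cache = self.stacks[p].forward(nhwc, training=training, rng=rng)
            feats.append(f)
            caches.append(cache)
        concat = np.concatenate(feats, axis=1)
        out, head_cache = self.head.forward(concat, training=training, rng=rng)
        sizes = [f.shape[1] for f in feats]
        return out[:, 0], (caches, head_cache, sizes)

    def backward(self, grad_out: np.ndarray, cache) -> None:
        caches, head_cache, sizes = cache
        g = self.head.backward(grad_out[:, None], head_cache)
        offs = np.cumsum([0] + sizes)
        for p, c, lo, hi in zip(self.spec.planes, caches, offs[:-1], offs[1:]):
            self.stacks[p].backward(np.ascontiguousarray(g[:, lo:hi]), c)

    def predict(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        out, _ = self.forward(batch, training=False)
        return out


@dataclass
class ParameterCount:
    """Exact trainable-scalar counts with a per-component breakdown."""

    total: int
    per_stack: dict[str, int]
    head: int
    batchnorm: int

    def __post_init__(self):
        assert self.total == sum(self.per_stack.values()) + self.head


def count_parameters(net: ProjectionNet) -> ParameterCount:
    seen: set[int] = set()
    per_stack: dict[str, int] = {}
    bn = 0
    for p in net.spec.planes:
        c = 0
        for lay in net.stacks[p].layers:
            for par in lay.params():
                if id(par) in seen:
                    continue
                seen.add(id(par))
                c += par.size
                if isinstance(lay, nn.BatchNorm2d):
                    bn += par.size
        per_stack[p] = c
    head = sum(par.size for par in net.head.params())
    return ParameterCount(sum(per_stack.values()) + head, per_stack, head, bn)


def build_model(spec: ModelSpec, seed: int = 0) -> ProjectionNet:
    return ProjectionNet(spec, seed=seed)


# -- checkpointing ------------------------------------------------------

def state_dict(net: ProjectionNet) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, par in enumerate(net.params()):
        state[f"{i:04d}:{par.name}"] = par.value.copy()
    # batchnorm running statistics are part of the checkpoint
    bn_idx = 0
    seen: set[int] = set()
    for plane in net.spec.planes:
        for lay in net.stacks[plane].layers:
            if isinstance(lay, nn.BatchNorm2d) and id(lay) not in seen:
                seen.add(id(lay))
                state[f"bnstat:{bn_idx}:mean"] = lay.running_mean.copy()
                state[f"bnstat:{bn_idx}:var"] = lay.running_var.copy()
                bn_idx += 1
    return state


def load_state(net: ProjectionNet, state: dict[str, np.ndarray]) -> None:
    for i, par in enumerate(net.params()):
        key = f"{i:04d}:{par.name}"
        if key not in state:
            raise ValueError(f"checkpoint missing parameter {par.name!r}")
        if state[key].shape != par.value.shape:
            raise ValueError(
                f"shape mismatch for {par.name!r}: checkpoint "
                f"{state[key].shape} vs model {par.value.shape}"
            )
        par.value = state[key].astype(np.float32).copy()
    bn_idx = 0
    seen: set[int] = set()
    for plane in net.spec.planes:
        for lay in net.stacks[plane].layers:
            if isinstance(lay, nn.BatchNorm2d) and id(lay) not in seen:
                seen.add(id(lay))
                lay.running_mean = state[f"bnstat:{bn_idx}:mean"].astype(np.float32).copy()
                lay.running_var = state[f"bnstat:{bn_idx}:var"].astype(np.float32).copy()
                bn_idx += 1


def save_weights(net: ProjectionNet, path: str | Path) -> Path:
    """Checkpoint: weights plus the embedded ModelSpec for self-description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = state_dict(net)
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo("spec.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, net.spec.to_json())
        for key in sorted(state):
            abuf = io.BytesIO()
            np.save(abuf, state[key])
            info = zipfile.ZipInfo(f"{key}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, abuf.getvalue())
    path.write_bytes(buf.getvalue())
    return path


def load_weights(path: str | Path, spec: ModelSpec | None = None) -> ProjectionNet:
    """Rebuild a network from a checkpoint.

    If ``spec`` is given it must match the stored one; a mismatch raises
    with the differing fields named.
    """
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        stored = ModelSpec.from_json(zf.read("spec.json").decode())
        if spec is not None and spec != stored:
            diffs = [f for f in ("depth", "width", "channels", "iso", "dropout_placement")
                     if getattr(spec, f) != getattr(stored, f)]
            raise ValueError(f"checkpoint spec mismatch in fields: {diffs}")
        state = {n[:-4]: np.load(io.BytesIO(zf.read(n)))
                 for n in zf.namelist() if n.endswith(".npy")}
    net = ProjectionNet(stored, seed=0)
    load_state(net, state)
    return net
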