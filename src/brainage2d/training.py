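"""Training protocol: MSE loss, Adam, fixed epoch budget, best-validation
checkpointing.

The whole packed training set is held resident in memory and reused
across epochs — the central efficiency property of the projection
approach (a handful of small 2D images per subject instead of a volume).
Training runs for the full epoch budget without halting; the weights are
recorded every time the validation loss reaches a new minimum, and that
best-validation state is the model used at test time.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .model import ProjectionNet, load_state, save_weights, state_dict
from .projection import PackedDataset, SplitArrays


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.003
    epochs: int = 400
    batch_size: int = 32
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainResult:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    best_val_loss: float
    best_state: dict[str, np.ndarray]
    best_checkpoint: Path | None
    wall_time: float

    def __post_init__(self):
        assert self.val_losses[self.best_epoch] == min(self.val_losses)


def _check_compatible(net: ProjectionNet, ds: PackedDataset) -> None:
    for p in net.spec.planes:
        want = net.spec.plane_channels(p)
        have = ds.plane_channels(p)
        if want != have:
            raise ValueError(
                f"channel mismatch for plane {p!r}: model expects "
                f"{[str(c) for c in want]}, dataset has {[str(c) for c in have]}"
            )


def _batches(n: int, batch_size: int, order: np.ndarray):
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


def predict(net: ProjectionNet, split: SplitArrays, batch_size: int = 64) -> np.ndarray:
    """Predicted ages, one finite scalar per subject in manifest order."""
    n = split.n
    preds = np.empty(n, dtype=np.float64)
    order = np.arange(n)
    for idx in _batches(n, batch_size, order):
        batch = {p: split.planes[p][idx] for p in net.spec.planes}
        preds[idx] = net.predict(batch)
    if not np.isfinite(preds).all():
        raise FloatingPointError("non-finite predictions")
    return preds


def _eval_mse(net: ProjectionNet, split: SplitArrays, batch_size: int) -> float:
    preds = predict(net, split, batch_size)
    return float(np.mean((preds - np.asarray(split.ages, float)) ** 2))


def train(net: ProjectionNet, dataset: PackedDataset, config: TrainConfig,
          checkpoint_path: str | Path | None = None,
          extra_train: SplitArrays | None = None) -> TrainResult:
    """Train on the ``train`` split, validating on ``val`` after each epoch.

    ``extra_train`` allows substituting an augmented training split while
    keeping validation untouched. Deterministic given ``config.seed`` on
    one device. Returns the loss trace and the best-validation state;
    the network itself is left at the final epoch, with the best state
    available via :func:`brainage2d.model.load_state`.
    """
    if "train" not in dataset.splits or "val" not in dataset.splits:
        raise ValueError("dataset needs 'train' and 'val' splits")
    train_split = extra_train if extra_train is not None else dataset.splits["train"]
    val_split = dataset.splits["val"]
    if train_split.n == 0 or val_split.n == 0:
        raise ValueError("empty split")
    _check_compatible(net, dataset)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7A)))
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    ages = np.asarray(train_split.ages, dtype=np.float32)
    n = train_split.n

    t0 = time.time()
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_state: dict[str, np.ndarray] = {}
    ckpt = Path(checkpoint_path) if checkpoint_path is not None else None

    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        losses, weights = [], []
        for idx in _batches(n, config.batch_size, order):
            batch = {p: train_split.planes[p][idx] for p in net.spec.planes}
            opt.zero_grad()
            pred, cache = net.forward(batch, training=True, rng=rng)
            loss, grad = nn.mse_loss(pred, ages[idx])
            net.backward(grad, cache)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        train_losses.append(float(np.average(losses, weights=weights)))
        val_mse = _eval_mse(net, val_split, max(config.batch_size, 64))
        val_losses.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            best_state = state_dict(net)
            if ckpt is not None:
                save_weights(net, ckpt)

    return TrainResult(train_losses, val_losses, best_epoch, float(best_val),
                       best_state, ckpt, time.time() - t0)


def restore_best(net: ProjectionNet, result: TrainResult) -> ProjectionNet:
    """Load the best-validation weights back into the network."""
    load_state(net, result.best_state)
    return net
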