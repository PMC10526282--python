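"""Accuracy metrics and the channel-ablation study.

``evaluate`` reports MAE and RMSE in years and the coefficient of
determination r² of predicted versus true age. ``run_ablation`` trains
one model per non-empty channel subset per learning rate, records the
best validation loss, and summarizes each channel's marginal
contribution: the average decrease in loss obtained by adding that
channel to a subset not containing it, taken over all ordered pairs
(S, S ∪ {c}) with S non-empty and over all learning rates jointly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec, build_model
from .projection import ChannelTag, PackedDataset, canonical_order
from .training import TrainConfig, train


@dataclass
class EvalReport:
    mae: float
    rmse: float
    r2: float
    n: int
    true_ages: np.ndarray
    predicted_ages: np.ndarray


def evaluate(true_ages, predicted_ages) -> EvalReport:
    """MAE, RMSE and r² of an age-prediction run."""
    y = np.asarray(true_ages, dtype=np.float64)
    yhat = np.asarray(predicted_ages, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 subjects to evaluate")
    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return EvalReport(mae, rmse, r2, int(y.size), y, yhat)


def export_scatter(report: EvalReport, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write (true, predicted) pairs as CSV and a scatter plot with identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    df = pd.DataFrame({"true_age": report.true_ages,
                       "predicted_age": report.predicted_ages})
    df.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(report.true_ages, report.predicted_ages, s=8, alpha=0.5)
    lims = [min(report.true_ages.min(), report.predicted_ages.min()),
            max(report.true_ages.max(), report.predicted_ages.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("true age (years)")
    ax.set_ylabel("predicted age (years)")
    ax.set_title(f"MAE {report.mae:.2f} y, RMSE {report.rmse:.2f} y, "
                 f"r² {report.r2:.3f} (n={report.n})")
    fig.tight_layout()
    png_path = prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path, csv_path


# -- ablation ----------------------------------------------------------

SubsetKey = tuple[ChannelTag, ...]


@dataclass
class AblationTable:
    """Losses per (channel subset, learning rate) and marginal contributions."""

    losses: dict[tuple[SubsetKey, float], float]
    contributions: dict[ChannelTag, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"channels": ",".join(map(str, subset)), "lr": lr, "loss": loss}
                for (subset, lr), loss in sorted(self.losses.items(),
                                                 key=lambda kv: (len(kv[0][0]), kv[0]))]
        return pd.DataFrame(rows)

    def contributions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"channel": str(c), "contribution": v}
             for c, v in sorted(self.contributions.items())]
        )


def marginal_contributions(losses: dict[tuple[SubsetKey, float], float]
                           ) -> dict[ChannelTag, float]:
    """Average loss decrease from adding each channel.

    For channel c: mean over all ordered pairs (S, S ∪ {c}) with c ∉ S,
    S non-empty, and over all learning rates, of loss(S) − loss(S ∪ {c}).
    """
    channels = sorted({c for (subset, _lr) in losses for c in subset})
    table: dict[float, dict[frozenset, float]] = {}
    for (subset, lr), loss in losses.items():
        table.setdefault(lr, {})[frozenset(subset)] = loss
    out: dict[ChannelTag, float] = {}
    for c in channels:
        deltas = []
        for lr, sub_losses in table.items():
            for s, loss_s in sub_losses.items():
                if c in s or not s:
                    continue
                s_with = s | {c}
                if s_with in sub_losses:
                    deltas.append(loss_s - sub_losses[s_with])
        if deltas:
            out[c] = float(np.mean(deltas))
    return out


def run_ablation(dataset: PackedDataset, spec_template: ModelSpec,
                 learning_rates=(0.003, 0.001), *, epochs: int = 10,
                 seed: int = 0, batch_size: int = 32,
                 max_subset_size: int | None = None) -> AblationTable:
    """Train one model per non-empty channel subset per learning rate.

    Uses the best-validation MSE of each training as the subset's loss.
    The 2^k − 1 non-empty subsets of the dataset's k channels are all
    evaluated (the empty set is untrainable).
    """
    channels = canonical_order(dataset.channels)
    if len(channels) < 2:
        raise ValueError("ablation needs at least 2 channels in the dataset")
    losses: dict[tuple[SubsetKey, float], float] = {}
    run_i = 0
    for r in range(1, len(channels) + 1):
        if max_subset_size is not None and r > max_subset_size:
            break
        for subset in itertools.combinations(channels, r):
            sub_ds = dataset.subset(subset)
            for lr in learning_rates:
                spec = replace(spec_template, channels=subset, iso=False)
                net = build_model(spec, seed=seed + run_i)
                cfg = TrainConfig(learning_rate=lr, epochs=epochs,
                                  batch_size=batch_size, seed=seed + run_i)
                result = train(net, sub_ds, cfg)
                losses[(subset, lr)] = result.best_val_loss
                run_i += 1
    return AblationTable(losses, marginal_contributions(losses))
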