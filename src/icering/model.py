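"""The ice-ring classifier.

A small CNN maps one normalized 80x80 value-vs-resolution histogram to a
score in [0, 1]; scores at or above the 0.5 threshold flag the window as
ice-ring contaminated.  The convolutional part is four blocks of two
'same'-padded convolutions (each followed by batch normalization and ReLU)
and a 2x2 max pool; the head is flatten -> dense -> dropout -> dense ->
dropout -> a single sigmoid unit.

Two networks are intended in practice, one per observable (amplitude and
intensity); the intensity network is usually obtained from the amplitude
network by transfer learning at a deliberately small learning rate (5e-4)
so the already-acquired spike-recognition features survive fine-tuning.

A dataset is called contaminated when *any* predictable window plot is
classified contaminated (logical OR over windows).  Blank or low-count
plots bypass the network and are reported nonpredictable with a warning.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .plotgen import IceRingPlot, IceRingRange, PlotConfig, make_plot, select_ranges
from .reflection_io import ReflectionSet, ValueKind

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "IceClassifier",
    "PlotPrediction",
    "DatasetPrediction",
    "build_network",
    "train",
    "transfer_train",
    "predict_plot",
    "predict_dataset",
    "aggregate_verdict",
    "smoothgrad",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network shape: 4 blocks x 2 convolutions, then a 2-layer dense head."""

    n_blocks: int = 4
    convs_per_block: int = 2
    filters_per_block: tuple[int, ...] = (4, 8, 16, 16)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.3
    batch_norm: bool = True
    input_shape: tuple[int, int] = (80, 80)

    def __post_init__(self) -> None:
        if self.n_blocks != 4 or self.convs_per_block != 2:
            raise ValueError("architecture is fixed at 4 blocks of 2 convolutions")
        if len(self.filters_per_block) != self.n_blocks:
            raise ValueError("need one filter count per block")
        if len(self.dense_units) != 2:
            raise ValueError("head has exactly two hidden dense layers")
        if self.pool_size != 2:
            raise ValueError("only 2x2 pooling is supported")
        side = self.input_shape[0]
        if self.input_shape[0] != self.input_shape[1] or side % 2**self.n_blocks:
            raise ValueError("input must be square and divisible by 2^n_blocks")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    """Training-loop parameters.

    80% of the plots go to the training split and 20% to validation; the
    weights from the best-validation-loss epoch are retained.  Transfer
    learning continues optimization at the moderate rate 5e-4.
    """

    split_fraction: float = 0.8
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    transfer_learning_rate: float = 0.0005
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or self.transfer_learning_rate <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class IceClassifier:
    """Architecture + learned state + the observable it was trained for."""

    architecture: ArchitectureConfig
    network: nn.Network
    kind: ValueKind = ValueKind.AMPLITUDE
    threshold: float = 0.5
    plot_config: PlotConfig = field(default_factory=PlotConfig)

    def score(self, grid: np.ndarray) -> float:
        """Score one normalized (80, 80) grid."""
        x = np.asarray(grid, dtype=np.float32)[None, :, :, None]
        return float(self.network.predict(x)[0])

    def score_batch(self, grids: np.ndarray) -> np.ndarray:
        x = np.asarray(grids, dtype=np.float32)[..., None]
        return self.network.predict(x)

    def layer_census(self) -> dict[str, int]:
        counts = {"conv": 0, "pool": 0, "batch_norm": 0, "dense_hidden": 0, "output": 0}
        dense_layers = [l for l in self.network.layers if isinstance(l, nn.Dense)]
        counts["conv"] = sum(isinstance(l, nn.Conv2D) for l in self.network.layers)
        counts["pool"] = sum(isinstance(l, nn.MaxPool2) for l in self.network.layers)
        counts["batch_norm"] = sum(isinstance(l, nn.BatchNorm) for l in self.network.layers)
        counts["dense_hidden"] = len(dense_layers) - 1
        counts["output"] = 1
        return counts


@dataclass
class PlotPrediction:
    """Network verdict for one window plot."""

    range_label: str
    score: float | None
    contaminated: bool | None
    predictable: bool
    reason: str = ""


@dataclass
class DatasetPrediction:
    plots: list[PlotPrediction]
    verdict: str  # "contaminated" | "clean" | "nonpredictable"


def build_network(cfg: ArchitectureConfig = ArchitectureConfig(), seed: int = 0) -> IceClassifier:
    """Freshly initialized classifier (seeded He init; untrained)."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for filters in cfg.filters_per_block:
        for _ in range(cfg.convs_per_block):
            layers.append(nn.Conv2D(c_in, filters, cfg.kernel_size, rng))
            if cfg.batch_norm:
                layers.append(nn.BatchNorm(filters))
            layers.append(nn.ReLU())
            c_in = filters
        layers.append(nn.MaxPool2())
    layers.append(nn.Flatten())
    side = cfg.input_shape[0] // 2**cfg.n_blocks
    n_in = side * side * c_in
    for units in cfg.dense_units:
        layers.append(nn.Dense(n_in, units, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout_rate, rng))
        n_in = units
    layers.append(nn.Dense(n_in, 1, rng))  # single logit; sigmoid applied at predict
    return IceClassifier(architecture=cfg, network=nn.Network(layers))


def _class_weights(y: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency weights (negative, positive), mean weight 1."""
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return 1.0, 1.0
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def _evaluate(net: nn.Network, x: np.ndarray, y: np.ndarray,
              w: np.ndarray, batch: int) -> tuple[float, float]:
    losses = []
    correct = 0
    for i in range(0, x.shape[0], batch):
        z = net.forward(x[i : i + batch], training=False)
        loss, _ = nn.bce_with_logits(z, y[i : i + batch], w[i : i + batch])
        losses.append(loss * min(batch, x.shape[0] - i))
        correct += int(((z >= 0).astype(int) == y[i : i + batch]).sum())
    return float(np.sum(losses) / x.shape[0]), correct / x.shape[0]


def _fit(
    model: IceClassifier,
    grids: np.ndarray,
    labels: np.ndarray,
    tc: TrainingConfig,
    lr: float,
) -> list[dict]:
    """Shared training loop: 80/20 split, weighted BCE, Adam, best-epoch weights."""
    x = np.asarray(grids, dtype=np.float32)[..., None]
    y = np.asarray(labels, dtype=np.int64)
    if x.shape[0] == 0:
        raise ValueError("empty training input")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0xFEED]))
    order = rng.permutation(x.shape[0])
    n_train = int(round(tc.split_fraction * x.shape[0]))
    tr, va = order[:n_train], order[n_train:]
    w_neg, w_pos = _class_weights(y[tr]) if tc.class_weighting else (1.0, 1.0)
    weights = np.where(y == 1, w_pos, w_neg).astype(np.float32)

    net = model.network
    opt = nn.Adam(net.all_params(), lr=lr)
    history: list[dict] = []
    best = (np.inf, net.get_weights())
    for epoch in range(tc.epochs):
        perm = tr[rng.permutation(tr.size)]
        batch_losses, batch_hits, seen = [], 0, 0
        for i in range(0, perm.size, tc.batch_size):
            idx = perm[i : i + tc.batch_size]
            z = net.forward(x[idx], training=True)
            loss, dz = nn.bce_with_logits(z, y[idx], weights[idx])
            net.backward(dz)
            opt.step(net.all_grads())
            batch_losses.append(loss * idx.size)
            batch_hits += int(((z >= 0).astype(int) == y[idx]).sum())
            seen += idx.size
        tr_loss, tr_acc = float(np.sum(batch_losses) / seen), batch_hits / seen
        va_loss, va_acc = _evaluate(net, x[va], y[va], weights[va], tc.batch_size)
        history.append(
            {"epoch": epoch, "loss": tr_loss, "accuracy": tr_acc,
             "val_loss": va_loss, "val_accuracy": va_acc}
        )
        if va_loss < best[0]:
            best = (va_loss, net.get_weights())
    if tc.epochs > 0:
        net.set_weights(best[1])
    return history


def train(
    grids: np.ndarray,
    labels: np.ndarray,
    arch: ArchitectureConfig = ArchitectureConfig(),
    tc: TrainingConfig = TrainingConfig(),
    kind: ValueKind = ValueKind.AMPLITUDE,
) -> tuple[IceClassifier, list[dict]]:
    """Train a fresh classifier on normalized (N, 80, 80) grids with 0/1 labels."""
    model = build_network(arch, seed=tc.seed)
    model.kind = ValueKind(kind)
    history = _fit(model, grids, labels, tc, lr=tc.learning_rate)
    return model, history


def transfer_train(
    base: IceClassifier,
    grids: np.ndarray,
    labels: np.ndarray,
    tc: TrainingConfig = TrainingConfig(),
    kind: ValueKind = ValueKind.INTENSITY,
) -> tuple[IceClassifier, list[dict]]:
    """Fine-tune ``base`` on a new corpus at the moderate transfer rate.

    Continues optimization from the base weights; the returned model's kind
    is the new corpus's observable.  Zero epochs returns a prediction-exact
    copy of the base.
    """
    model = build_network(base.architecture, seed=tc.seed)
    model.network.set_weights(base.network.get_weights())
    model.kind = ValueKind(kind)
    model.plot_config = base.plot_config
    history = _fit(model, grids, labels, tc, lr=tc.transfer_learning_rate)
    return model, history


def predict_plot(model: IceClassifier, plot: IceRingPlot) -> PlotPrediction:
    """Classify one plot; blank and low-count plots bypass the network."""
    if plot.blank:
        warnings.warn(
            f"window {plot.range_label}: blank plot, marked nonpredictable",
            stacklevel=2,
        )
        return PlotPrediction(plot.range_label, None, None, False, "blank")
    if plot.low_count:
        warnings.warn(
            f"window {plot.range_label}: only {plot.n_in_range} reflections, "
            "marked nonpredictable",
            stacklevel=2,
        )
        return PlotPrediction(plot.range_label, None, None, False, "low_count")
    if plot.kind != model.kind:
        warnings.warn(
            f"window {plot.range_label}: plot kind {plot.kind.value} differs from "
            f"model kind {model.kind.value}; predicting anyway",
            stacklevel=2,
        )
    s = model.score(plot.grid)
    return PlotPrediction(plot.range_label, s, s >= model.threshold, True)


def predict_dataset(
    model: IceClassifier,
    rset: ReflectionSet,
    table: list[IceRingRange],
    cfg: PlotConfig | None = None,
) -> DatasetPrediction:
    """Per-window predictions plus the OR-aggregated dataset verdict."""
    cfg = cfg or model.plot_config
    windows = select_ranges(rset, table, pad=cfg.x_pad)
    preds = [predict_plot(model, make_plot(rset, w, cfg)) for w in windows]
    return DatasetPrediction(preds, aggregate_verdict(preds))


def aggregate_verdict(preds: list[PlotPrediction]) -> str:
    """OR rule: one contaminated predictable window contaminates the dataset;
    with no predictable window at all the dataset is nonpredictable."""
    predictable = [p for p in preds if p.predictable]
    if not predictable:
        return "nonpredictable"
    if any(p.contaminated for p in predictable):
        return "contaminated"
    return "clean"


def smoothgrad(
    model: IceClassifier,
    plot: IceRingPlot | np.ndarray,
    n_samples: int = 16,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Sensitivity map: mean |d score / d pixel| over noise-perturbed copies.

    ``noise_sigma`` is a fraction of the input's value range; with
    ``n_samples=1, noise_sigma=0`` this is the plain input gradient.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    grid = plot.grid if isinstance(plot, IceRingPlot) else np.asarray(plot)
    x = grid.astype(np.float32)[None, :, :, None]
    span = float(grid.max() - grid.min())
    rng = np.random.default_rng(seed)
    net = model.network
    acc = np.zeros_like(grid, dtype=float)
    for _ in range(n_samples):
        noise = 0.0
        if noise_sigma > 0:
            noise = rng.normal(0.0, noise_sigma * span, size=x.shape).astype(np.float32)
        z = net.forward(x + noise, training=False)
        s = nn.sigmoid(z)
        dz = (s * (1.0 - s)).astype(np.float32)  # d sigmoid / d logit
        dx = net.backward(dz)
        acc += np.abs(dx[0, :, :, 0])
    return acc / n_samples


# ---------------------------------------------------------------------------
# persistence: one .npz holding configs (JSON) + weights

def save_model(model: IceClassifier, path: str | Path) -> None:
    """Serialize architecture, featurization config, kind and weights."""
    meta = {
        "architecture": dataclasses.asdict(model.architecture),
        "plot_config": dataclasses.asdict(model.plot_config),
        "kind": model.kind.value,
        "threshold": model.threshold,
        "format_version": 1,
    }
    arrays = {f"w{i}": a for i, a in enumerate(model.network.get_weights())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> IceClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    arch_d = meta["architecture"]
    arch_d["filters_per_block"] = tuple(arch_d["filters_per_block"])
    arch_d["dense_units"] = tuple(arch_d["dense_units"])
    arch_d["input_shape"] = tuple(arch_d["input_shape"])
    arch = ArchitectureConfig(**arch_d)
    model = build_network(arch, seed=0)
    model.network.set_weights(arrays)
    model.kind = ValueKind(meta["kind"])
    model.threshold = float(meta["threshold"])
    model.plot_config = PlotConfig(**meta["plot_config"])
    return model
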