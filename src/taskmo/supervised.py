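"""Supervised learning-based model observers: CNN and SLNN.

The CNN is a stack of size-preserving 3x3 convolutional layers (no
downscaling, so no high-frequency content is discarded), each followed by
LeakyReLU, ending in a single fully connected unit with a sigmoid whose
output is read as the posterior probability of signal presence.  The SLNN
is one fully connected layer over the vectorized image with a sigmoid
output — a nonlinear-output observer whose pre-activation weights form an
implied linear template comparable to the Hotelling template.

Both are trained with Adam on binary cross-entropy under a strict
train–validation–test protocol.  ``cnn_structure_search`` reproduces the
brute-force architecture search over depth x filters, selecting the
configuration with minimum mean validation cross-entropy.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .synthetic import DetectionDataset

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "TrainedObserver",
    "build_supervised_observer",
    "train_supervised",
    "cnn_structure_search",
    "count_parameters",
]

_DEPTHS = range(2, 11)
_FILTERS = (4, 8, 16)


@dataclass(frozen=True)
class CNNConfig:
    """CNN structure within the searched space: depth 2–10, filters {4,8,16}."""

    depth: int = 2
    filters: int = 8
    kernel: int = 3
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.depth not in _DEPTHS:
            raise ValueError(f"depth must be in {list(_DEPTHS)}")
        if self.filters not in _FILTERS:
            raise ValueError(f"filters must be one of {_FILTERS}")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedObserver:
    """A trained probabilistic observer: score(images) in (0, 1)."""

    model: nn.Sequential
    kind: str
    config: object
    train_config: TrainConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    fit_seconds: float = 0.0

    def score(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Posterior probability of signal presence per image."""
        x = _as_nhwc(images)
        out = np.empty(len(x), dtype=np.float64)
        for start in range(0, len(x), batch_size):
            out[start : start + batch_size] = self.model.forward(
                x[start : start + batch_size]
            ).ravel()
        return out

    def linear_template(self) -> np.ndarray:
        """Pre-activation weights of an SLNN as an image-domain template."""
        if self.kind != "slnn":
            raise ValueError("linear template only defined for the SLNN")
        dense = next(l for l in self.model.layers if isinstance(l, nn.Dense))
        return dense.W[:, 0].astype(np.float64).copy()


def _as_nhwc(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError("images must be (n, rows, cols)")
    return arr


def build_supervised_observer(
    kind: str, config: CNNConfig | None = None, image_shape=(64, 64), seed: int = 0
) -> nn.Sequential:
    """Untrained CNN or SLNN for the given image shape."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    H, W = image_shape
    kind = kind.lower()
    if kind == "slnn":
        model = nn.Sequential(
            [nn.Flatten(), nn.Dense(H * W, 1, rng), nn.Sigmoid()]
        )
    elif kind == "cnn":
        config = config or CNNConfig()
        layers = [nn.Conv2D(1, config.filters, rng, config.kernel),
                  nn.LeakyReLU(config.leaky_slope)]
        for _ in range(config.depth - 1):
            layers += [nn.Conv2D(config.filters, config.filters, rng, config.kernel),
                       nn.LeakyReLU(config.leaky_slope)]
        layers += [nn.Flatten(), nn.Dense(config.filters * H * W, 1, rng), nn.Sigmoid()]
        layers[0].needs_input_grad = False
        model = nn.Sequential(layers)
    else:
        raise ValueError(f"unknown observer kind {kind!r}; use 'cnn' or 'slnn'")
    return model


def count_parameters(model: nn.Sequential) -> int:
    return int(sum(p.size for p in model.params()))


def _check_disjoint(a: np.ndarray, b: np.ndarray) -> None:
    ha = {row.tobytes() for row in a.reshape(len(a), -1)}
    hb = {row.tobytes() for row in b.reshape(len(b), -1)}
    if ha & hb:
        raise ValueError("train and validation sets share images; splits must be disjoint")


def _eval_bce(model: nn.Sequential, x: np.ndarray, y: np.ndarray,
              batch_size: int = 256) -> float:
    total, n = 0.0, 0
    for start in range(0, len(x), batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        loss, _ = nn.bce_loss(model.forward(xb), yb)
        total += loss * len(xb)
        n += len(xb)
    return total / n


def train_supervised(
    model: nn.Sequential,
    train_ds: DetectionDataset,
    val_ds: DetectionDataset,
    cfg: TrainConfig,
    kind: str = "cnn",
    config: object = None,
) -> TrainedObserver:
    """Train a CNN/SLNN observer with Adam on binary cross-entropy.

    Records per-epoch train and validation loss; deterministic for a fixed
    seed and thread configuration.  Raises on non-disjoint splits or NaN
    loss.
    """
    x_tr = _as_nhwc(train_ds.images)
    y_tr = np.asarray(train_ds.labels, dtype=np.float32).reshape(-1, 1)
    x_va = _as_nhwc(val_ds.images)
    y_va = np.asarray(val_ds.labels, dtype=np.float32).reshape(-1, 1)
    _check_disjoint(x_tr, x_va)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    opt = nn.Adam(model.params(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    records = []
    t0 = time.perf_counter()
    for epoch in range(cfg.epochs):
        ep_loss, n_seen = 0.0, 0
        for idx in nn.iterate_minibatches(len(x_tr), cfg.batch_size, rng):
            loss, grad = nn.bce_loss(model.forward(x_tr[idx]), y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check input scaling"
                )
            model.backward(grad)
            opt.step(model.grads())
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss = _eval_bce(model, x_va, y_va)
        records.append(
            {"epoch": epoch, "train_loss": ep_loss / n_seen, "val_loss": val_loss}
        )
    fit_seconds = time.perf_counter() - t0
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "val_loss"])
    return TrainedObserver(model, kind, config, cfg, history, fit_seconds)


def cnn_structure_search(
    train_ds: DetectionDataset,
    val_ds: DetectionDataset,
    test_ds: DetectionDataset,
    depths=range(2, 11),
    filters=(4, 8, 16),
    repeats: int = 20,
    train_cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[CNNConfig, pd.DataFrame]:
    """Brute-force CNN structure search over (depth, filters).

    Every configuration is trained ``repeats`` times (fresh seeds); the
    configuration minimizing the mean validation cross-entropy is selected.
    Returns the selected config and a tidy per-run table (depth, filters,
    repeat, val_ce, test_auc, fit_seconds).
    """
    from .evaluation import mann_whitney_auc

    depths = list(depths)
    filters = list(filters)
    if not depths or not filters:
        raise ValueError("empty structure search space")
    shape = (train_ds.grid.n_rows, train_ds.grid.n_cols)
    y_test = np.asarray(test_ds.labels)
    rows = []
    for depth in depths:
        for n_filt in filters:
            config = CNNConfig(depth=depth, filters=n_filt)
            for rep in range(repeats):
                run_seed = int(
                    np.random.SeedSequence([seed, depth, n_filt, rep]).generate_state(1)[0]
                    % (2**31)
                )
                model = build_supervised_observer("cnn", config, shape, seed=run_seed)
                obs = train_supervised(
                    model, train_ds, val_ds,
                    TrainConfig(
                        epochs=train_cfg.epochs,
                        batch_size=train_cfg.batch_size,
                        learning_rate=train_cfg.learning_rate,
                        seed=run_seed,
                    ),
                    kind="cnn", config=config,
                )
                t = obs.score(test_ds.images)
                rows.append({
                    "depth": depth,
                    "filters": n_filt,
                    "repeat": rep,
                    "val_ce": obs.history["val_loss"].iloc[-1],
                    "test_auc": mann_whitney_auc(t[y_test == 0], t[y_test == 1]),
                    "fit_seconds": obs.fit_seconds,
                })
    table = pd.DataFrame(rows)
    means = table.groupby(["depth", "filters"])["val_ce"].mean()
    best_depth, best_filters = means.idxmin()
    return CNNConfig(depth=int(best_depth), filters=int(best_filters)), table
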