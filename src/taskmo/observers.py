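"""Uniform observer factories for experiments and the CLI.

Each factory has the signature ``factory(train_ds, val_ds, seed) -> obs``
where ``obs.score(images)`` returns a continuous test statistic, so the
learning-curve machinery can treat the Hotelling observer, the supervised
networks, and the self-supervised two-stage observers interchangeably.
"""

from __future__ import annotations

import numpy as np

from .hotelling import (LinearObserver, apply_linear_observer,
                        estimate_class_moments, ho_template, known_covariance_ho)
from .selfsup import (CDAEConfig, DEFAULT_C_GRID, DEFAULT_SIGMA_GRID,
                      fit_ssl_observer)
from .supervised import (CNNConfig, TrainConfig, build_supervised_observer,
                         train_supervised)
from .synthetic import (BackgroundSpec, DetectionDataset, PixelGrid,
                        SignalSpecSKE, ske_profile)

__all__ = [
    "LinearScorer",
    "make_sample_ho",
    "make_known_cov_ho",
    "make_cnn",
    "make_slnn",
    "make_cdae_svm",
    "make_pca_svm",
    "OBSERVER_FACTORIES",
]


class LinearScorer:
    """Adapter giving a LinearObserver the common score() interface."""

    def __init__(self, obs: LinearObserver):
        self.obs = obs

    def score(self, images: np.ndarray) -> np.ndarray:
        return apply_linear_observer(self.obs, images)


def make_sample_ho(ridge="auto"):
    def factory(train_ds: DetectionDataset, val_ds, seed: int) -> LinearScorer:
        moments = estimate_class_moments(train_ds)
        return LinearScorer(ho_template(moments, ridge=ridge))

    return factory


def make_known_cov_ho(grid: PixelGrid, bg_spec: BackgroundSpec, signal_image: np.ndarray):
    """Oracle HO from the analytically known background covariance.

    ``signal_image`` is the mean class difference on the *stored* (normalized)
    intensity scale; the spectral template is scale-invariant in AUC.
    """
    obs = known_covariance_ho(grid, bg_spec, signal_image)

    def factory(train_ds=None, val_ds=None, seed: int = 0) -> LinearScorer:
        return LinearScorer(obs)

    return factory


def make_cnn(config: CNNConfig | None = None, epochs: int = 50, batch_size: int = 64):
    config = config or CNNConfig()

    def factory(train_ds, val_ds, seed: int):
        shape = (train_ds.grid.n_rows, train_ds.grid.n_cols)
        model = build_supervised_observer("cnn", config, shape, seed=seed)
        return train_supervised(
            model, train_ds, val_ds,
            TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed),
            kind="cnn", config=config,
        )

    return factory


def make_slnn(epochs: int = 50, batch_size: int = 64):
    def factory(train_ds, val_ds, seed: int):
        shape = (train_ds.grid.n_rows, train_ds.grid.n_cols)
        model = build_supervised_observer("slnn", None, shape, seed=seed)
        return train_supervised(
            model, train_ds, val_ds,
            TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed),
            kind="slnn",
        )

    return factory


def make_cdae_svm(config: CDAEConfig | None = None, C_grid=DEFAULT_C_GRID,
                  sigma_grid=DEFAULT_SIGMA_GRID, max_epochs: int = 30,
                  patience: int = 5, pretext_images=None):
    """``pretext_images``: fixed unlabeled pool for the encoder; when given,
    the labeled set only feeds the SVM stage (the self-supervised economy)."""

    def factory(train_ds, val_ds, seed: int):
        return fit_ssl_observer(
            train_ds, val_ds, config=config, C_grid=C_grid,
            sigma_grid=sigma_grid, max_epochs=max_epochs, patience=patience,
            seed=seed, extractor="cdae", pretext_images=pretext_images,
        )

    return factory


def make_pca_svm(config: CDAEConfig | None = None, C_grid=DEFAULT_C_GRID,
                 sigma_grid=DEFAULT_SIGMA_GRID, pretext_images=None):
    def factory(train_ds, val_ds, seed: int):
        return fit_ssl_observer(
            train_ds, val_ds, config=config, C_grid=C_grid,
            sigma_grid=sigma_grid, seed=seed, extractor="pca",
            pretext_images=pretext_images,
        )

    return factory


#: Default factory constructors by observer name (CLI / config use).
OBSERVER_FACTORIES = {
    "ho": make_sample_ho,
    "cnn": make_cnn,
    "slnn": make_slnn,
    "cdae-svm": make_cdae_svm,
    "pca-svm": make_pca_svm,
}
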