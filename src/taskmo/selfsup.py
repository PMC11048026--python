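"""Self-supervised model observer: CDAE features + RBF-SVM classifier.

The pretext stage trains a convolutional denoising autoencoder (CDAE) to
reconstruct clean images from pixel-masked corruptions, with no labels
involved: the encoder is a stack of size-preserving 3x3 convolutions
(LeakyReLU) followed by a fully connected bottleneck of ``latent_units``;
the decoder mirrors it back to image space with a sigmoid output, valid
because images live on [0, 1].  The objective is the pixelwise cross
entropy between the clean image and the reconstruction of its corrupted
version, plus an L2 weight-decay penalty ``lambda * ||W||^2`` over all
weight matrices (biases excluded).  Early stopping on a held-out
reconstruction loss sets the epoch count.

The downstream stage standardizes the latent features and fits an RBF-SVM,
selecting the penalty C and kernel width sigma (convention
``k(x, y) = exp(-||x - y||^2 / (2 sigma^2))``) by stratified 5-fold
cross-validated AUC over a log-spaced grid, ties broken toward small C
then small sigma.

A PCA baseline replaces the encoder by the top-k principal directions —
the subspace an optimal linear one-layer autoencoder under squared error
converges to.  ``cdae_bayesian_search`` optimizes the architecture
(depth, filters, latent units) by Gaussian-process expected improvement
on the validation reconstruction loss.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from scipy.stats import norm

from . import nn

__all__ = [
    "CDAEConfig",
    "SVMConfig",
    "CDAE",
    "SSLObserver",
    "corrupt_inputs",
    "build_cdae",
    "train_cdae",
    "encode",
    "fit_pca",
    "svm_grid_search",
    "cdae_bayesian_search",
    "fit_ssl_observer",
    "ssl_observer_score",
    "DEFAULT_C_GRID",
    "DEFAULT_SIGMA_GRID",
]

# grids match the reported search ranges: C in 1e-1..1e7, sigma in 1e-2..1e2
DEFAULT_C_GRID = tuple(10.0**k for k in range(-1, 8))
DEFAULT_SIGMA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class CDAEConfig:
    """CDAE architecture and pretext-training hyperparameters.

    The default (depth 1, 16 filters, 25 latent units, lambda 1e-3) is the
    architecture the Bayesian search selects on the reference tasks.
    """

    depth: int = 1
    filters: int = 16
    latent_units: int = 25
    kernel: int = 3
    corruption_rate: float = 0.05
    weight_decay: float = 1e-3
    leaky_slope: float = 0.01
    learning_rate: float = 3e-3

    def __post_init__(self):
        if not 1 <= self.depth <= 8:
            raise ValueError("depth must be in 1..8")
        if self.filters not in (4, 8, 16):
            raise ValueError("filters must be one of (4, 8, 16)")
        if not 2 <= self.latent_units <= 32:
            raise ValueError("latent_units must be in 2..32")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")
        if self.weight_decay < 0:
            raise ValueError("weight_decay (lambda) must be >= 0")


@dataclass(frozen=True)
class SVMConfig:
    """Fitted RBF-SVM hyperparameters; sigma is the kernel width."""

    C: float
    sigma: float
    cv_folds: int = 5
    scoring: str = "auc"

    def __post_init__(self):
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be > 0")

    @property
    def gamma(self) -> float:
        """sklearn's gamma under k = exp(-gamma ||x-y||^2)."""
        return 1.0 / (2.0 * self.sigma**2)


def corrupt_inputs(
    images: np.ndarray, rate: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Masking corruption: each pixel independently zeroed with probability
    ``rate``.  Returns a new array; the input is untouched."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("corruption rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.array(images, copy=True)
    if rate > 0:
        mask = rng.random(out.shape) < rate
        out[mask] = 0.0
    return out


class CDAE:
    """Encoder/decoder pair; ``encode`` is the deterministic feature map."""

    def __init__(self, config: CDAEConfig, image_shape=(64, 64), seed: int = 0):
        self.config = config
        self.image_shape = tuple(image_shape)
        H, W = self.image_shape
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        enc = [nn.Conv2D(1, config.filters, rng, config.kernel),
               nn.LeakyReLU(config.leaky_slope)]
        for _ in range(config.depth - 1):
            enc += [nn.Conv2D(config.filters, config.filters, rng, config.kernel),
                    nn.LeakyReLU(config.leaky_slope)]
        enc += [nn.Flatten(), nn.Dense(config.filters * H * W, config.latent_units, rng)]
        enc[0].needs_input_grad = False
        dec = [nn.Dense(config.latent_units, config.filters * H * W, rng),
               nn.LeakyReLU(config.leaky_slope),
               nn.Reshape((H, W, config.filters))]
        for _ in range(config.depth - 1):
            dec += [nn.Conv2D(config.filters, config.filters, rng, config.kernel),
                    nn.LeakyReLU(config.leaky_slope)]
        dec += [nn.Conv2D(config.filters, 1, rng, config.kernel), nn.Sigmoid()]
        self.encoder = nn.Sequential(enc)
        self.decoder = nn.Sequential(dec)
        self.net = nn.Sequential([self.encoder, self.decoder])
        self.trained = False
        self.history: pd.DataFrame | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def encode(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Latent features (n, latent_units); corruption is never applied here."""
        if not self.trained:
            raise RuntimeError("CDAE is untrained; call train_cdae first")
        x = _as_nhwc(images)
        out = np.empty((len(x), self.config.latent_units), dtype=np.float64)
        for start in range(0, len(x), batch_size):
            out[start : start + batch_size] = self.encoder.forward(
                x[start : start + batch_size]
            )
        return out

    def weight_sq_norm(self) -> float:
        return self.net.weight_sq_norm()


def _as_nhwc(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., None]
    return arr


def build_cdae(config: CDAEConfig | None = None, image_shape=(64, 64), seed: int = 0) -> CDAE:
    """Untrained CDAE; config defaults to the selected reference architecture."""
    return CDAE(config or CDAEConfig(), image_shape, seed)


def train_cdae(
    model: CDAE,
    images: np.ndarray,
    val_images: np.ndarray,
    max_epochs: int = 200,
    patience: int = 5,
    batch_size: int = 64,
    seed: int = 0,
) -> CDAE:
    """Pretext training: reconstruct clean images from pixel-masked inputs.

    Minimizes pixelwise cross-entropy + lambda ||W||^2, labels never seen.
    The cross-entropy is summed over pixels and averaged over the batch, so
    the classical lambda range [0, 0.1] weighs the penalty against the
    whole-image reconstruction term rather than a single pixel's.
    Fresh corruption masks are drawn per minibatch; validation inputs use a
    fixed corruption mask so the early-stopping criterion is comparable
    across epochs.  Stops when validation reconstruction loss has not
    improved for ``patience`` epochs.
    """
    cfg = model.config
    x = _as_nhwc(images)
    xv = _as_nhwc(val_images)
    if x.min() < 0.0 or x.max() > 1.0 or xv.min() < 0.0 or xv.max() > 1.0:
        raise ValueError("CDAE inputs must lie in [0, 1] for the cross-entropy loss")
    ss = np.random.SeedSequence(seed)
    shuffle_rng, corrupt_rng, val_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    xv_corr = corrupt_inputs(xv, cfg.corruption_rate, val_rng)

    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    lam = cfg.weight_decay
    n_pix = int(np.prod(x.shape[1:]))  # pixel-sum loss scale
    weight_mats = model.net.weight_matrices()
    records = []
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(max_epochs):
        ep_loss, n_seen = 0.0, 0
        for idx in nn.iterate_minibatches(len(x), batch_size, shuffle_rng):
            clean = x[idx]
            corrupted = corrupt_inputs(clean, cfg.corruption_rate, corrupt_rng)
            recon = model.forward(corrupted)
            loss, grad = nn.bce_loss(recon, clean)
            loss *= n_pix
            grad *= n_pix
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite reconstruction loss at epoch {epoch}")
            model.net.backward(grad)
            grads = model.net.grads()
            if lam > 0:  # weight decay on weight matrices only
                params = model.net.params()
                for p, g in zip(params, grads):
                    if any(p is w for w in weight_mats):
                        g += 2.0 * lam * p
            opt.step(grads)
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss = _eval_recon(model, xv_corr, xv, batch_size)
        records.append({"epoch": epoch, "train_loss": ep_loss / n_seen,
                        "val_loss": val_loss,
                        "weight_sq_norm": model.weight_sq_norm()})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = [p.copy() for p in model.net.params()]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best_params is not None:
        for p, bp in zip(model.net.params(), best_params):
            p[...] = bp
    model.history = pd.DataFrame(records)
    model.trained = True
    return model


def _eval_recon(model: CDAE, x_in: np.ndarray, x_target: np.ndarray,
                batch_size: int) -> float:
    n_pix = int(np.prod(x_in.shape[1:]))
    total, n = 0.0, 0
    for start in range(0, len(x_in), batch_size):
        recon = model.forward(x_in[start : start + batch_size])
        loss, _ = nn.bce_loss(recon, x_target[start : start + batch_size])
        total += loss * n_pix * len(recon)
        n += len(recon)
    return total / n


def encode(model: CDAE, images: np.ndarray) -> np.ndarray:
    return model.encode(images)


class PCAFeatures:
    """Top-k principal-direction feature map (linear-autoencoder baseline)."""

    def __init__(self, pca: PCA):
        self._pca = pca

    @property
    def components(self) -> np.ndarray:
        return self._pca.components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self._pca.explained_variance_ratio_

    def encode(self, images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        return self._pca.transform(arr.reshape(len(arr), -1))

    transform = encode


def fit_pca(images: np.ndarray, k: int) -> PCAFeatures:
    """Mean-centered PCA with k orthonormal components ordered by variance."""
    arr = np.asarray(images, dtype=np.float64)
    X = arr.reshape(len(arr), -1)
    if k > min(len(X) - 1, X.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(n-1, M) = {min(len(X) - 1, X.shape[1])}"
        )
    return PCAFeatures(PCA(n_components=k, svd_solver="auto").fit(X))


def svm_grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    seed: int = 0,
    cv_folds: int = 5,
    groups: np.ndarray | None = None,
) -> tuple[Pipeline, SVMConfig, pd.DataFrame]:
    """Stratified k-fold CV AUC over the (C, sigma) grid; refit the best.

    Features are standardized inside each fold (scaler in the pipeline).
    When ``groups`` is given (e.g. shared-background pair ids), whole groups
    stay within one fold, so paired realizations never straddle the CV
    boundary.  Ties are broken toward the smallest C, then the smallest
    sigma.  Returns (fitted pipeline, selected config, full CV table).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present for SVM fitting")
    if len(C_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    if groups is not None:
        folds = _grouped_folds(np.asarray(groups).ravel(), cv_folds, seed)
    else:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))

    rows = []
    best = None  # (auc, C, sigma)
    for C in sorted(C_grid):
        for sigma in sorted(sigma_grid):
            cfg = SVMConfig(C=C, sigma=sigma, cv_folds=cv_folds)
            aucs = []
            for tr, te in folds:
                pipe = _svm_pipeline(cfg)
                pipe.fit(X[tr], y[tr])
                t = pipe.decision_function(X[te])
                from .evaluation import mann_whitney_auc

                aucs.append(mann_whitney_auc(t[y[te] == 0], t[y[te] == 1]))
            mean_auc = float(np.mean(aucs))
            rows.append({"C": C, "sigma": sigma, "cv_auc_mean": mean_auc,
                         "cv_auc_sd": float(np.std(aucs))})
            # strict improvement keeps the smallest C then sigma on ties
            if best is None or mean_auc > best[0] + 1e-12:
                best = (mean_auc, C, sigma)
    _, C_best, sigma_best = best
    cfg = SVMConfig(C=C_best, sigma=sigma_best, cv_folds=cv_folds)
    pipe = _svm_pipeline(cfg).fit(X, y)
    return pipe, cfg, pd.DataFrame(rows)


def _grouped_folds(groups: np.ndarray, n_folds: int, seed: int):
    """Shuffled group-wise fold assignment (train_idx, test_idx) list."""
    uniq = np.unique(groups)
    order = np.random.default_rng(seed).permutation(uniq)
    chunks = np.array_split(order, n_folds)
    folds = []
    for chunk in chunks:
        mask = np.isin(groups, chunk)
        folds.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return folds


def _svm_pipeline(cfg: SVMConfig) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)),
    ])


def cdae_bayesian_search(
    images: np.ndarray,
    trials: int = 20,
    depth_bounds=(1, 8),
    filters_choices=(4, 8, 16),
    latent_bounds=(2, 32),
    seed: int = 0,
    max_epochs: int = 30,
    patience: int = 3,
    val_fraction: float = 0.2,
    n_initial: int = 5,
) -> tuple[CDAEConfig, pd.DataFrame]:
    """Sequential model-based architecture search for the CDAE.

    A Matern Gaussian process models validation reconstruction loss over
    (depth, filters, latent units); candidates maximize expected
    improvement over the integer-valued space.  Each trial resamples the
    train/validation split.  Deterministic for a fixed seed.  Returns the
    best config and the per-trial log.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    x = _as_nhwc(images)
    space = [
        (d, f, l)
        for d in range(depth_bounds[0], depth_bounds[1] + 1)
        for f in filters_choices
        for l in range(latent_bounds[0], latent_bounds[1] + 1)
    ]
    if not space:
        raise ValueError("empty architecture search space")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    space_arr = np.array(space, dtype=float)
    # normalize coordinates for GP length scales
    lo, hi = space_arr.min(axis=0), space_arr.max(axis=0)
    scale = np.where(hi > lo, hi - lo, 1.0)
    space_norm = (space_arr - lo) / scale

    evaluated: dict[tuple, float] = {}
    log = []

    def objective(cand: tuple, trial_idx: int) -> float:
        d, f, l = cand
        trial_ss = np.random.SeedSequence([seed, trial_idx])
        split_rng = np.random.default_rng(trial_ss.spawn(1)[0])
        n_val = max(1, int(len(x) * val_fraction))
        perm = split_rng.permutation(len(x))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        cfg = CDAEConfig(depth=int(d), filters=int(f), latent_units=int(l))
        model = build_cdae(cfg, x.shape[1:3], seed=int(trial_ss.generate_state(1)[0] % 2**31))
        t0 = time.perf_counter()
        train_cdae(model, x[tr_idx], x[val_idx], max_epochs=max_epochs,
                   patience=patience, seed=int(trial_ss.generate_state(2)[1] % 2**31))
        val_loss = float(model.history["val_loss"].min())
        log.append({"trial": trial_idx, "depth": int(d), "filters": int(f),
                    "latent_units": int(l), "val_recon_loss": val_loss,
                    "fit_seconds": time.perf_counter() - t0})
        return val_loss

    n_init = min(n_initial, trials, len(space))
    init_idx = rng.choice(len(space), size=n_init, replace=False)
    for i, si in enumerate(init_idx):
        cand = space[si]
        evaluated[cand] = objective(cand, i)

    for trial in range(n_init, trials):
        done = [space.index(c) for c in evaluated]
        X_done = space_norm[done]
        y_done = np.array([evaluated[space[i]] for i in done])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.ones(3)),
            alpha=1e-4, normalize_y=True, random_state=trial,
        )
        gp.fit(X_done, y_done)
        remaining = [i for i in range(len(space)) if space[i] not in evaluated]
        if not remaining:
            break
        mu, sd = gp.predict(space_norm[remaining], return_std=True)
        best_y = y_done.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best_y - mu) / sd
            ei = (best_y - mu) * norm.cdf(z) + sd * norm.pdf(z)
        ei[sd < 1e-12] = 0.0
        cand = space[remaining[int(np.argmax(ei))]]
        evaluated[cand] = objective(cand, trial)

    best_cand = min(evaluated, key=evaluated.get)
    best_cfg = CDAEConfig(depth=int(best_cand[0]), filters=int(best_cand[1]),
                          latent_units=int(best_cand[2]))
    return best_cfg, pd.DataFrame(log)


@dataclass
class SSLObserver:
    """Two-stage observer: trained feature extractor + fitted RBF-SVM."""

    extractor: CDAE | PCAFeatures
    svm: Pipeline
    svm_config: SVMConfig
    provenance: dict = field(default_factory=dict)

    def score(self, images: np.ndarray) -> np.ndarray:
        """Continuous SVM decision values on latent features (ROC statistic)."""
        return self.svm.decision_function(self.extractor.encode(images))


def fit_ssl_observer(
    train_ds,
    val_ds,
    config: CDAEConfig | None = None,
    C_grid=DEFAULT_C_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    max_epochs: int = 30,
    patience: int = 5,
    seed: int = 0,
    extractor: str = "cdae",
    pretext_images: np.ndarray | None = None,
) -> SSLObserver:
    """End-to-end fit: pretext CDAE (labels unseen) or PCA, then SVM stage.

    ``pretext_images`` is the unlabeled image pool for feature learning —
    in the self-supervised paradigm this pool is typically much larger than
    the labeled set, since no annotation is consumed.  When omitted, the
    pooled train+validation images are used.  The SVM grid search uses the
    training labels only.
    """
    config = config or CDAEConfig()
    ss = np.random.SeedSequence(seed)
    s_cdae, s_svm = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    if pretext_images is None:
        pretext = np.concatenate([train_ds.images, val_ds.images])
    else:
        pretext = np.asarray(pretext_images)
    n_val = max(1, int(0.1 * len(pretext)))
    if extractor == "cdae":
        model = build_cdae(config, (train_ds.grid.n_rows, train_ds.grid.n_cols),
                           seed=s_cdae)
        train_cdae(model, pretext[n_val:], pretext[:n_val],
                   max_epochs=max_epochs, patience=patience, seed=s_cdae)
        feats = model.encode(train_ds.images)
    elif extractor == "pca":
        model = fit_pca(pretext, config.latent_units)
        feats = model.encode(train_ds.images)
    else:
        raise ValueError("extractor must be 'cdae' or 'pca'")
    svm, svm_cfg, cv_table = svm_grid_search(
        feats, train_ds.labels, C_grid, sigma_grid, seed=s_svm,
        groups=getattr(train_ds, "pair_ids", None),
    )
    prov = {
        "extractor": extractor,
        "cdae_config": asdict(config),
        "svm_config": {"C": svm_cfg.C, "sigma": svm_cfg.sigma},
        "n_train": len(train_ds),
        "seed": seed,
        "cv_table": cv_table,
    }
    return SSLObserver(model, svm, svm_cfg, prov)


def ssl_observer_score(obs: SSLObserver, images: np.ndarray) -> np.ndarray:
    return obs.score(images)
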