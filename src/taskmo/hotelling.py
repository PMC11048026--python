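"""Hotelling observer (HO): optimal linear observer for binary detection.

The HO template is the population Fisher discriminant

    w = (1/2 (K0 + K1) + ridge * I)^-1  (mean_present - mean_absent),

applied to a vectorized image f as the scalar test statistic t = w^T f.
Two estimation routes are provided:

* sample HO — class moments estimated from a labeled training ensemble,
  with ridge-regularized inversion (an accurate raw covariance would need
  on the order of 10 * M^2 training images, unattainable at M = 4096);
* known-covariance HO — the oracle template from the analytically known
  background covariance of the synthetic task; for FFT-synthesized
  stationary backgrounds the covariance is block-circulant, so K^-1 s is
  computed exactly in the frequency domain in O(M log M).

For equal-covariance Gaussian classes, detectability has the closed form
SNR = sqrt(s^T K^-1 s) and AUC = Phi(SNR / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import ndtr

from .synthetic import BackgroundSpec, DetectionDataset, PixelGrid, background_spectrum

__all__ = [
    "ClassMoments",
    "LinearObserver",
    "estimate_class_moments",
    "ho_template",
    "known_covariance_ho",
    "apply_linear_observer",
    "analytic_detectability",
    "spectral_detectability",
    "default_ridge",
]


@dataclass
class ClassMoments:
    """First and second sample moments per class (0 = absent, 1 = present)."""

    mean_absent: np.ndarray
    mean_present: np.ndarray
    K0: np.ndarray
    K1: np.ndarray
    n0: int
    n1: int

    @property
    def delta_mean(self) -> np.ndarray:
        return self.mean_present - self.mean_absent

    @property
    def pooled_covariance(self) -> np.ndarray:
        return 0.5 * (self.K0 + self.K1)


@dataclass
class LinearObserver:
    """Linear template observer t = w^T f."""

    w: np.ndarray
    source: str = "sample-HO"  # sample-HO | known-K-HO | other
    ridge: float = 0.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.all(np.isfinite(self.w)):
            raise ValueError("template contains non-finite entries")


def estimate_class_moments(ds: DetectionDataset) -> ClassMoments:
    """Unbiased per-class sample means and covariances from a labeled dataset."""
    X = ds.flat.astype(np.float64)
    y = np.asarray(ds.labels)
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("need >= 2 samples in each class to estimate moments")
    X0, X1 = X[y == 0], X[y == 1]
    K0 = np.cov(X0, rowvar=False)
    K1 = np.cov(X1, rowvar=False)
    K0 = 0.5 * (K0 + K0.T)
    K1 = 0.5 * (K1 + K1.T)
    return ClassMoments(X0.mean(axis=0), X1.mean(axis=0), K0, K1, n0, n1)


def default_ridge(K: np.ndarray) -> float:
    """Default ridge strength 1e-3 * trace(K) / M."""
    return 1e-3 * np.trace(K) / K.shape[0]


def ho_template(
    moments: ClassMoments | None = None,
    *,
    K: np.ndarray | None = None,
    delta_mean: np.ndarray | None = None,
    ridge: float | str = 0.0,
    source: str | None = None,
) -> LinearObserver:
    """Hotelling template from class moments or a known covariance.

    ``ridge`` may be a non-negative scalar or ``"auto"`` (1e-3 tr(K)/M).
    Raises a diagnostic error when the pooled covariance is singular at
    ridge = 0.
    """
    if moments is not None:
        K = moments.pooled_covariance
        delta_mean = moments.delta_mean
        source = source or "sample-HO"
    else:
        if K is None or delta_mean is None:
            raise ValueError("provide either moments or (K, delta_mean)")
        K = 0.5 * (np.asarray(K, float) + np.asarray(K, float).T)
        source = source or "known-K-HO"
    if ridge == "auto":
        ridge = default_ridge(K)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    A = K + ridge * np.eye(K.shape[0])
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
        w = scipy.linalg.cho_solve((c, low), np.asarray(delta_mean, float))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; pass ridge > 0 (e.g. ridge='auto') "
            "or use a shrinkage estimate"
        ) from exc
    return LinearObserver(w=w, source=source, ridge=float(ridge))


def known_covariance_ho(
    grid: PixelGrid, bg_spec: BackgroundSpec, signal: np.ndarray
) -> LinearObserver:
    """Oracle HO template w = K^-1 s via the frequency domain.

    Valid for the stationary Gaussian background kinds, whose covariance is
    block-circulant with eigenvalue map S(f): K^-1 s = ifft2(fft2(s) / S).
    ``signal`` is the HU-domain (or consistently scaled) mean difference
    image.
    """
    if bg_spec.kind == "lumpy":
        raise ValueError("known-covariance HO requires a Gaussian background kind")
    s_spec = background_spectrum(grid, bg_spec)
    sig = np.asarray(signal, float).reshape(grid.n_rows, grid.n_cols)
    w = np.fft.ifft2(np.fft.fft2(sig) / s_spec).real
    return LinearObserver(w=w.ravel(), source="known-K-HO", ridge=0.0)


def apply_linear_observer(obs: LinearObserver, images: np.ndarray) -> np.ndarray:
    """Test statistics t_i = w^T f_i for an image stack or single image."""
    arr = np.asarray(images, dtype=float)
    single = arr.ndim == 2
    flat = arr.reshape(1, -1) if single else arr.reshape(arr.shape[0], -1)
    if flat.shape[1] != obs.w.size:
        raise ValueError(
            f"image size {flat.shape[1]} does not match template length {obs.w.size}"
        )
    t = flat @ obs.w
    return t[0] if single else t


def analytic_detectability(K: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Closed-form (SNR, AUC) of the HO on equal-covariance Gaussian classes.

    SNR = sqrt(s^T K^-1 s); AUC = Phi(SNR / sqrt(2)).  K must be positive
    definite.
    """
    K = 0.5 * (np.asarray(K, float) + np.asarray(K, float).T)
    s = np.asarray(s, float).ravel()
    try:
        c, low = scipy.linalg.cho_factor(K, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance must be positive definite") from exc
    snr2 = float(s @ scipy.linalg.cho_solve((c, low), s))
    snr = np.sqrt(max(snr2, 0.0))
    return snr, float(ndtr(snr / np.sqrt(2.0)))


def spectral_detectability(
    grid: PixelGrid, bg_spec: BackgroundSpec, signal: np.ndarray
) -> tuple[float, float]:
    """(SNR, AUC) of the known-covariance HO via the circulant spectrum.

    Equivalent to :func:`analytic_detectability` with the exact block-
    circulant K, but O(M log M): SNR^2 = sum |fft2(s)|^2 / S(f) / M.
    """
    if bg_spec.kind == "lumpy":
        raise ValueError("spectral detectability requires a Gaussian background kind")
    s_spec = background_spectrum(grid, bg_spec)
    sig_f = np.fft.fft2(np.asarray(signal, float).reshape(grid.n_rows, grid.n_cols))
    snr2 = float(np.sum(np.abs(sig_f) ** 2 / s_spec) / grid.n_pixels)
    snr = np.sqrt(snr2)
    return snr, float(ndtr(snr / np.sqrt(2.0)))
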