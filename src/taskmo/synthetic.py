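"""Synthetic binary signal-detection tasks on CT-like image ensembles.

Implements the background-known-statistically (BKS) paradigm: stochastic
backgrounds with a controllable second-order correlation structure, plus
parametric signals inserted additively.  Two signal paradigms are supported:

* SKE (signal known exactly): a rotationally symmetric nodule profile
  ``A_s * (1 - ||r - r_c||^2 / R^2)^z`` inside radius ``R``, zero outside,
  emulating a low-attenuation ground-glass opacity.
* SKS (signal known statistically): a rotated anisotropic Gaussian ellipse
  whose orientation is drawn per image from a discrete angle set.

Backgrounds are stationary Gaussian random fields synthesized by spectral
filtering of white noise on the FFT torus, so their covariance is known in
closed form (block-circulant), which enables exact Hotelling-observer
oracles.  An optional lumpy component (Poisson number of Gaussian blobs,
wrapped on the torus) adds non-Gaussian texture.

All stored images are mapped to [0, 1] by a fixed affine Hounsfield-unit
window recorded in the dataset provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "PixelGrid",
    "SignalSpecSKE",
    "SignalSpecSKS",
    "BackgroundSpec",
    "DetectionDataset",
    "ske_profile",
    "sks_profile",
    "sample_backgrounds",
    "background_spectrum",
    "analytic_background_covariance",
    "build_detection_dataset",
    "save_dataset",
    "load_dataset",
    "export_tiff",
    "DEFAULT_HU_WINDOW",
]

#: Fixed affine normalization window (HU): lo -> 0.0, hi -> 1.0, clipped.
DEFAULT_HU_WINDOW = (-1000.0, 500.0)


@dataclass(frozen=True)
class PixelGrid:
    """Square pixel raster with physical spacing.

    Coordinates are 0-based pixel indices; the default signal center sits at
    ``((n_rows - 1) / 2, (n_cols - 1) / 2)``.  Physical lengths (e.g. the SKE
    radius in mm) are converted to pixels via ``pixel_spacing``.
    """

    n_rows: int = 64
    n_cols: int = 64
    pixel_spacing: float = 0.7  # mm / pixel, typical chest-CT recon FOV

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def center(self) -> tuple[float, float]:
        return ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column index arrays, shape (n_rows, n_cols)."""
        return np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )


@dataclass(frozen=True)
class SignalSpecSKE:
    """Rotationally symmetric nodule profile (signal-known-exactly).

    ``amplitude`` in HU, ``radius`` in mm (converted through the grid's pixel
    spacing), ``exponent`` dimensionless; the profile is exactly zero outside
    the support radius.
    """

    amplitude: float = -60.0
    radius: float = 4.0  # mm
    exponent: float = 4.0
    center: tuple[float, float] | None = None  # pixel coords; None -> grid center

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.exponent <= 0:
            raise ValueError("exponent must be > 0")


@dataclass(frozen=True)
class SignalSpecSKS:
    """Rotated anisotropic Gaussian ellipse (signal-known-statistically).

    Widths are in pixels; the orientation of each signal-present image is
    drawn uniformly from ``angle_set`` (degrees).
    """

    amplitude: float = -60.0
    sigma_x: float = 5.0
    sigma_y: float = 1.5
    angle_set: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    center: tuple[float, float] | None = None

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be > 0")
        if len(self.angle_set) == 0:
            raise ValueError("angle_set must be non-empty")


@dataclass(frozen=True)
class BackgroundSpec:
    """Stationary stochastic background model.

    kind:
        ``"white"`` — iid Gaussian pixels;
        ``"correlated-gaussian"`` — Gaussian random field with radially
        symmetric power spectrum ``f^alpha * exp(-f^2 / f_c^2)`` (f in
        cycles/pixel), synthesized by FFT spectral filtering so the
        covariance is exactly block-circulant;
        ``"lumpy"`` — correlated-gaussian base plus a Poisson number of
        Gaussian blobs wrapped on the torus (no closed-form covariance
        implemented).

    ``noise_sd`` is the per-pixel standard deviation of the Gaussian part in
    HU; ``mean_level`` the stationary mean in HU.
    """

    kind: str = "correlated-gaussian"
    mean_level: float = -850.0
    noise_sd: float = 56.0
    spectrum_alpha: float = 0.0
    spectrum_cutoff: float = 0.35  # cycles / pixel
    #: fraction of the total pixel variance carried by a white (uncorrelated)
    #: spectral floor, emulating detector/quantum noise on top of the
    #: structured texture component
    spectrum_floor: float = 0.0
    lump_count_mean: float = 20.0
    lump_width: float = 4.0  # pixels
    lump_magnitude: float = 30.0  # HU

    _KINDS = ("white", "correlated-gaussian", "lumpy")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown background kind {self.kind!r}; one of {self._KINDS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DetectionDataset:
    """Labeled image ensemble for a binary detection task.

    ``images`` are unit-normalized (``[0, 1]``) float32 arrays of shape
    (n, n_rows, n_cols); ``labels`` is int8 with 1 = signal present.
    ``angles`` holds the per-image sampled SKS orientation (NaN for
    signal-absent images; None for SKE tasks).  ``provenance`` records the
    generating specs, seed, and the affine HU window so the dataset is fully
    regenerable.
    """

    images: np.ndarray
    labels: np.ndarray
    grid: PixelGrid
    angles: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)
    #: shared-background pair id per image (absent/present siblings match);
    #: splits and cross-validation must keep siblings together to avoid
    #: leaking background realizations across folds
    pair_ids: np.ndarray | None = None

    def __post_init__(self):
        if self.images.ndim != 3:
            raise ValueError("images must be (n, rows, cols)")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.images.shape[1:] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("image shape inconsistent with grid")
        if not np.isin(np.unique(self.labels), [0, 1]).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def flat(self) -> np.ndarray:
        """Images as (n, M) row vectors."""
        return self.images.reshape(len(self.images), -1)

    def subset(self, indices: np.ndarray) -> "DetectionDataset":
        indices = np.asarray(indices)
        return DetectionDataset(
            images=self.images[indices],
            labels=self.labels[indices],
            grid=self.grid,
            angles=None if self.angles is None else self.angles[indices],
            provenance={**self.provenance, "subset_of_n": len(self)},
            pair_ids=None if self.pair_ids is None else self.pair_ids[indices],
        )


# ---------------------------------------------------------------------------
# signal profiles


def ske_profile(grid: PixelGrid, spec: SignalSpecSKE) -> np.ndarray:
    """Evaluate the SKE nodule profile on the grid (HU image).

    The profile is ``A_s * (1 - d^2/R^2)^z`` for pixel distance ``d <= R``
    (R converted from mm to pixels) and exactly zero outside.
    """
    r_pix = spec.radius / grid.pixel_spacing
    if r_pix < 1.0:
        raise ValueError(
            f"signal radius {spec.radius} mm is below one pixel spacing "
            f"({grid.pixel_spacing} mm): unresolvable"
        )
    cy, cx = spec.center if spec.center is not None else grid.center
    rows, cols = grid.coords()
    d2 = (rows - cy) ** 2 + (cols - cx) ** 2
    inside = d2 <= r_pix**2
    prof = np.zeros((grid.n_rows, grid.n_cols))
    prof[inside] = spec.amplitude * (1.0 - d2[inside] / r_pix**2) ** spec.exponent
    return prof


def sks_profile(grid: PixelGrid, spec: SignalSpecSKS, angle: float) -> np.ndarray:
    """Evaluate the SKS elliptical profile at a given orientation (degrees).

    ``A_s * exp(-(R_phi u)^T D^{-1} (R_phi u))`` with ``u = r - r_c`` and
    ``D = diag(sigma_x^2, sigma_y^2)`` (no 1/2 factor in the exponent).
    """
    if angle not in spec.angle_set:
        raise ValueError(f"angle {angle} not in configured angle_set {spec.angle_set}")
    cy, cx = spec.center if spec.center is not None else grid.center
    rows, cols = grid.coords()
    # (x, y) = (col offset, row offset); rotation by phi in image plane
    dx = cols - cx
    dy = rows - cy
    phi = np.deg2rad(angle)
    xr = np.cos(phi) * dx + np.sin(phi) * dy
    yr = -np.sin(phi) * dx + np.cos(phi) * dy
    q = (xr / spec.sigma_x) ** 2 + (yr / spec.sigma_y) ** 2
    return spec.amplitude * np.exp(-q)


# ---------------------------------------------------------------------------
# stochastic backgrounds


def background_spectrum(grid: PixelGrid, spec: BackgroundSpec) -> np.ndarray:
    """Target noise power spectrum on the FFT grid, scaled so the stationary
    per-pixel variance equals ``noise_sd**2``.

    Returns the (n_rows, n_cols) array of circulant-covariance eigenvalues
    ``S(f)``; the covariance acts as ``K x = ifft2(S * fft2(x))``.
    """
    if spec.kind == "white":
        return np.full((grid.n_rows, grid.n_cols), spec.noise_sd**2)
    fr = np.fft.fftfreq(grid.n_rows)
    fc = np.fft.fftfreq(grid.n_cols)
    f = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)
    shape = np.empty_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** spec.spectrum_alpha * np.exp(
        -(f[nz] ** 2) / spec.spectrum_cutoff**2
    )
    # DC bin: continue the spectrum flat from the lowest resolved frequency
    # (a diverging DC term would put all power into the mean offset).
    fmin = f[nz].min()
    shape[~nz] = fmin**spec.spectrum_alpha * np.exp(-(fmin**2) / spec.spectrum_cutoff**2)
    # normalize: per-pixel variance of the circulant field = mean eigenvalue
    shape /= shape.mean()
    if not 0.0 <= spec.spectrum_floor <= 1.0:
        raise ValueError("spectrum_floor must be in [0, 1]")
    shape = (1.0 - spec.spectrum_floor) * shape + spec.spectrum_floor
    return shape * spec.noise_sd**2


def sample_backgrounds(
    grid: PixelGrid, spec: BackgroundSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent stationary background realizations (HU).

    Correlated fields are built by filtering white noise in the frequency
    domain with ``sqrt(S)``, so the target spectrum holds in closed form and
    realizations are reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n, grid.n_rows, grid.n_cols)
    if spec.kind == "white":
        return spec.mean_level + spec.noise_sd * rng.standard_normal(shape)

    s = background_spectrum(grid, spec)
    # b = ifft2(h * fft2(w)) with white w has circulant covariance with
    # eigenvalue map h^2, so h = sqrt(S) reproduces the target spectrum.
    h = np.sqrt(s)
    w = rng.standard_normal(shape)
    fields = np.fft.ifft2(h[None] * np.fft.fft2(w), axes=(1, 2)).real
    out = spec.mean_level + fields
    if spec.kind == "lumpy":
        out += _lumpy_component(grid, spec, n, rng)
    return out


def _lumpy_component(
    grid: PixelGrid, spec: BackgroundSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-count Gaussian blobs, wrapped on the torus for stationarity."""
    rows, cols = grid.coords()
    out = np.zeros((n, grid.n_rows, grid.n_cols))
    counts = rng.poisson(spec.lump_count_mean, size=n)
    for i in range(n):
        for _ in range(counts[i]):
            cy = rng.uniform(0, grid.n_rows)
            cx = rng.uniform(0, grid.n_cols)
            dy = np.minimum(np.abs(rows - cy), grid.n_rows - np.abs(rows - cy))
            dx = np.minimum(np.abs(cols - cx), grid.n_cols - np.abs(cols - cx))
            out[i] += spec.lump_magnitude * np.exp(
                -(dy**2 + dx**2) / (2 * spec.lump_width**2)
            )
    out -= spec.lump_count_mean * 2 * np.pi * spec.lump_width**2 \
        * spec.lump_magnitude / grid.n_pixels  # recenter to zero mean
    return out


def analytic_background_covariance(grid: PixelGrid, spec: BackgroundSpec) -> np.ndarray:
    """Exact M x M pixel covariance of the stationary background field.

    For the FFT-synthesized fields the covariance is block-circulant with
    circulant blocks (hence block-Toeplitz); entry (i, j) depends only on the
    toroidal lag between pixels i and j.  Only Gaussian kinds have a closed
    form; the lumpy kind raises.
    """
    if spec.kind == "lumpy":
        raise ValueError("no closed-form covariance for lumpy backgrounds")
    if spec.kind == "white":
        return spec.noise_sd**2 * np.eye(grid.n_pixels)
    s = background_spectrum(grid, spec)
    acov = np.fft.ifft2(s).real  # autocovariance map over toroidal lags
    rows, cols = grid.coords()
    ri = rows.ravel()
    ci = cols.ravel()
    dlag_r = (ri[:, None] - ri[None, :]) % grid.n_rows
    dlag_c = (ci[:, None] - ci[None, :]) % grid.n_cols
    K = acov[dlag_r, dlag_c]
    return 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# dataset assembly and I/O


def normalize_hu(images_hu: np.ndarray, window=DEFAULT_HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return np.clip((images_hu - lo) / (hi - lo), 0.0, 1.0)


def denormalize(images01: np.ndarray, window=DEFAULT_HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return images01 * (hi - lo) + lo


def build_detection_dataset(
    grid: PixelGrid,
    bg_spec: BackgroundSpec,
    sig_spec: SignalSpecSKE | SignalSpecSKS,
    n_pairs: int,
    paradigm: str | None = None,
    seed: int = 0,
    window=DEFAULT_HU_WINDOW,
    paired: bool = True,
) -> DetectionDataset:
    """Assemble a balanced BKS detection dataset of ``2 * n_pairs`` images.

    With ``paired=True`` each absent/present pair shares one background
    realization, so present minus paired absent equals the signal profile
    exactly — the construction the generator contract is verified against.
    With ``paired=False`` every image gets an independent background, which
    is how training ensembles for learning experiments should be built: on
    paired data the class-mean difference equals the signal with zero
    noise, an unrealistic shortcut for any learned observer.

    SKS orientations are drawn independently per signal-present image,
    uniformly over the angle set.  Intensities are mapped to [0, 1] by the
    affine HU window recorded in provenance.  Image order: indices
    [0, n_pairs) absent, [n_pairs, 2n) present.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if paradigm is None:
        paradigm = "SKE" if isinstance(sig_spec, SignalSpecSKE) else "SKS"
    paradigm = paradigm.upper()
    if paradigm not in ("SKE", "SKS"):
        raise ValueError("paradigm must be SKE or SKS")
    if paradigm == "SKE" and not isinstance(sig_spec, SignalSpecSKE):
        raise TypeError("SKE paradigm requires a SignalSpecSKE")
    if paradigm == "SKS" and not isinstance(sig_spec, SignalSpecSKS):
        raise TypeError("SKS paradigm requires a SignalSpecSKS")

    _check_signal_inside(grid, sig_spec)

    ss = np.random.SeedSequence(seed)
    bg_rng, angle_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    if paired:
        bgs = sample_backgrounds(grid, bg_spec, n_pairs, bg_rng)
        bgs_present = bgs
    else:
        both = sample_backgrounds(grid, bg_spec, 2 * n_pairs, bg_rng)
        bgs, bgs_present = both[:n_pairs], both[n_pairs:]

    angles = None
    if paradigm == "SKE":
        profile = ske_profile(grid, sig_spec)
        present = bgs_present + profile[None]
    else:
        drawn = angle_rng.choice(np.asarray(sig_spec.angle_set, dtype=float), size=n_pairs)
        present = bgs_present.copy()
        for a in sig_spec.angle_set:
            mask = drawn == a
            if mask.any():
                present[mask] += sks_profile(grid, sig_spec, a)[None]
        angles = np.concatenate([np.full(n_pairs, np.nan), drawn])

    images_hu = np.concatenate([bgs, present])
    images = normalize_hu(images_hu, window).astype(np.float32)
    labels = np.concatenate(
        [np.zeros(n_pairs, dtype=np.int8), np.ones(n_pairs, dtype=np.int8)]
    )
    pair_ids = np.tile(np.arange(n_pairs), 2) if paired else None
    provenance = {
        "background": asdict(bg_spec),
        "signal": asdict(sig_spec),
        "signal_kind": type(sig_spec).__name__,
        "grid": asdict(grid),
        "paradigm": paradigm,
        "n_pairs": n_pairs,
        "seed": seed,
        "hu_window": list(window),
        "paired": paired,
    }
    return DetectionDataset(images, labels, grid, angles, provenance, pair_ids)


def _check_signal_inside(grid: PixelGrid, sig_spec) -> None:
    cy, cx = sig_spec.center if sig_spec.center is not None else grid.center
    if isinstance(sig_spec, SignalSpecSKE):
        r_pix = sig_spec.radius / grid.pixel_spacing
        if (cy - r_pix < 0 or cy + r_pix > grid.n_rows - 1
                or cx - r_pix < 0 or cx + r_pix > grid.n_cols - 1):
            raise ValueError("SKE signal support extends beyond the grid")
    else:
        reach = 3.0 * max(sig_spec.sigma_x, sig_spec.sigma_y)
        if (cy - reach < 0 or cy + reach > grid.n_rows - 1
                or cx - reach < 0 or cx + reach > grid.n_cols - 1):
            raise ValueError("SKS signal (3 sigma) extends beyond the grid")


def save_dataset(ds: DetectionDataset, path: str | Path) -> None:
    """Write a dataset to HDF5 (/images, /labels, /angles, meta attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images)
        f.create_dataset("labels", data=ds.labels)
        if ds.angles is not None:
            f.create_dataset("angles", data=ds.angles)
        if ds.pair_ids is not None:
            f.create_dataset("pair_ids", data=ds.pair_ids)
        f.attrs["provenance"] = json.dumps(ds.provenance)
        f.attrs["grid"] = json.dumps(asdict(ds.grid))


def load_dataset(path: str | Path) -> DetectionDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            images = f["images"][...]
            labels = f["labels"][...]
            angles = f["angles"][...] if "angles" in f else None
            pair_ids = f["pair_ids"][...] if "pair_ids" in f else None
            provenance = json.loads(f.attrs["provenance"])
            grid = PixelGrid(**json.loads(f.attrs["grid"]))
    except (KeyError, OSError) as exc:
        raise ValueError(f"corrupt or invalid dataset file {path}: {exc}") from exc
    if len(images) != len(labels):
        raise ValueError(
            f"corrupt dataset {path}: {len(images)} images vs {len(labels)} labels"
        )
    return DetectionDataset(images, labels, grid, angles, provenance, pair_ids)


def export_tiff(ds: DetectionDataset, path: str | Path) -> None:
    """Export the image stack as a multi-page float32 TIFF for inspection."""
    tifffile.imwrite(path, ds.images.astype(np.float32))
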