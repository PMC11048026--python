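"""ROC/AUC machinery, split protocol, and observer learning-curve experiments.

The AUC is estimated by the Mann–Whitney statistic — the fraction of
(absent, present) score pairs ranked correctly, ties counted 1/2 — which
equals the trapezoidal area under the empirical ROC curve exactly.
Confidence intervals are stratified bootstrap percentiles.  The
learning-curve experiment retrains each observer on growing training
subsets with a fixed shared test set, against a constant Hotelling
reference estimated once.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .synthetic import DetectionDataset

__all__ = [
    "ROCResult",
    "LearningCurve",
    "mann_whitney_auc",
    "roc_points",
    "auc_confidence_interval",
    "evaluate_scores",
    "train_val_test_split",
    "learning_curve_experiment",
]


@dataclass
class ROCResult:
    auc: float
    roc_points: np.ndarray  # (k, 2) ordered (FPR, TPR)
    n_absent: int
    n_present: int
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95


@dataclass
class LearningCurve:
    """Tidy per-(observer, size, repeat) AUC table with a constant HO reference."""

    table: pd.DataFrame
    reference_auc: float
    sizes: list[int] = field(default_factory=list)
    repeats: int = 0


def _check_classes(t_absent, t_present):
    t0 = np.asarray(t_absent, dtype=float).ravel()
    t1 = np.asarray(t_present, dtype=float).ravel()
    if len(t0) == 0 or len(t1) == 0:
        raise ValueError("both classes must be non-empty")
    return t0, t1


def mann_whitney_auc(t_absent, t_present) -> float:
    """P(t_present > t_absent) with ties counted 1/2 (rank-sum estimator)."""
    t0, t1 = _check_classes(t_absent, t_present)
    ranks = rankdata(np.concatenate([t0, t1]))
    r1 = ranks[len(t0):].sum()
    return float((r1 - len(t1) * (len(t1) + 1) / 2.0) / (len(t0) * len(t1)))


def roc_points(t_absent, t_present) -> np.ndarray:
    """Empirical ROC staircase from sweeping the decision threshold.

    Returns ordered (FPR, TPR) points including (0,0) and (1,1); the
    trapezoidal integral of these points equals :func:`mann_whitney_auc`.
    """
    t0, t1 = _check_classes(t_absent, t_present)
    y = np.concatenate([np.zeros(len(t0)), np.ones(len(t1))])
    fpr, tpr, _ = roc_curve(y, np.concatenate([t0, t1]), drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def auc_confidence_interval(
    t_absent,
    t_present,
    level: float = 0.95,
    method: str = "bootstrap",
    seed: int = 0,
    n_boot: int = 1000,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the Mann–Whitney AUC."""
    if method != "bootstrap":
        raise ValueError("only the 'bootstrap' method is implemented")
    t0, t1 = _check_classes(t_absent, t_present)
    if len(t0) < 10 or len(t1) < 10:
        raise ValueError("need >= 10 samples per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        s0 = t0[rng.integers(0, len(t0), len(t0))]
        s1 = t1[rng.integers(0, len(t1), len(t1))]
        stats[b] = mann_whitney_auc(s0, s1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, ci: bool = False, seed: int = 0,
    level: float = 0.95,
) -> ROCResult:
    """Bundle AUC, ROC points and (optionally) a bootstrap CI for a score set."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    t0, t1 = scores[labels == 0], scores[labels == 1]
    auc = mann_whitney_auc(t0, t1)
    pts = roc_points(t0, t1)
    interval = auc_confidence_interval(t0, t1, level=level, seed=seed) if ci else None
    return ROCResult(auc, pts, len(t0), len(t1), interval, level)


def train_val_test_split(
    ds: DetectionDataset,
    sizes: tuple[int, int, int],
    seed: int = 0,
) -> tuple[DetectionDataset, DetectionDataset, DetectionDataset]:
    """Disjoint class-stratified train/validation/test subsets.

    ``sizes`` are image counts (each must be even so classes balance).  When
    the dataset is paired (absent/present images sharing one background
    realization), whole pairs are allocated to a single split so no
    background realization leaks between training and evaluation.
    """
    n_train, n_val, n_test = sizes
    for s in sizes:
        if s % 2 != 0:
            raise ValueError("split sizes must be even for class balance")
    if sum(sizes) > len(ds):
        raise ValueError(
            f"requested {sum(sizes)} images but dataset holds {len(ds)}"
        )
    labels = np.asarray(ds.labels)
    rng = np.random.default_rng(seed)
    if ds.pair_ids is not None:
        uniq = np.unique(ds.pair_ids)
        order = rng.permutation(uniq)
        if len(uniq) < sum(sizes) // 2:
            raise ValueError("not enough pairs for the requested splits")
        parts = []
        off = 0
        for s in sizes:
            half = s // 2
            chosen = set(order[off : off + half])
            off += half
            take = np.flatnonzero([pid in chosen for pid in ds.pair_ids])
            parts.append(ds.subset(take))
        return tuple(parts)
    idx0 = rng.permutation(np.flatnonzero(labels == 0))
    idx1 = rng.permutation(np.flatnonzero(labels == 1))
    if min(len(idx0), len(idx1)) < sum(sizes) // 2:
        raise ValueError("not enough samples per class for the requested splits")
    parts = []
    off0 = off1 = 0
    for s in sizes:
        half = s // 2
        take = np.concatenate([idx0[off0 : off0 + half], idx1[off1 : off1 + half]])
        off0 += half
        off1 += half
        parts.append(ds.subset(np.sort(take)))
    return tuple(parts)


def learning_curve_experiment(
    observers: dict,
    pool_ds: DetectionDataset,
    test_ds: DetectionDataset,
    val_ds: DetectionDataset,
    sizes=(100, 200, 500, 1000, 2500, 5000),
    repeats: int = 5,
    seed: int = 0,
    reference_auc: float | None = None,
) -> LearningCurve:
    """AUC of each observer versus training-set size (image counts).

    ``observers`` maps name -> factory; ``factory(train_ds, val_ds, seed)``
    must return an object with ``score(images) -> statistics``.  For each
    (observer, size, repeat) a fresh stratified training subset is drawn
    from the pool and the observer is evaluated on the fixed shared test
    set.  Fitting time is recorded (never asserted).  Training failures are
    recorded as missing AUC with the diagnostic, not silently dropped.
    ``reference_auc`` is the constant Hotelling reference line.
    """
    sizes = sorted(sizes)
    if sizes[-1] > len(pool_ds):
        raise ValueError("largest training size exceeds the pool")
    y_test = np.asarray(test_ds.labels)
    labels = np.asarray(pool_ds.labels)
    idx0_all = np.flatnonzero(labels == 0)
    idx1_all = np.flatnonzero(labels == 1)
    rows = []
    for name, factory in observers.items():
        for size in sizes:
            for rep in range(repeats):
                name_key = zlib.crc32(name.encode())  # stable across runs
                sub_seed = int(
                    np.random.SeedSequence(
                        [seed, name_key, size, rep]
                    ).generate_state(1)[0] % 2**31
                )
                rng = np.random.default_rng(sub_seed)
                half = size // 2
                take = np.concatenate([
                    rng.choice(idx0_all, half, replace=False),
                    rng.choice(idx1_all, size - half, replace=False),
                ])
                train_sub = pool_ds.subset(np.sort(take))
                t0 = time.perf_counter()
                try:
                    obs = factory(train_sub, val_ds, sub_seed)
                    t = np.asarray(obs.score(test_ds.images)).ravel()
                    auc = mann_whitney_auc(t[y_test == 0], t[y_test == 1])
                    err = ""
                except Exception as exc:  # recorded, not silent
                    auc = np.nan
                    err = f"{type(exc).__name__}: {exc}"
                rows.append({
                    "observer": name, "size": size, "repeat": rep,
                    "auc": auc, "fit_seconds": time.perf_counter() - t0,
                    "seed": sub_seed, "error": err,
                })
    table = pd.DataFrame(rows)
    return LearningCurve(table, reference_auc if reference_auc is not None else np.nan,
                         list(sizes), repeats)
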