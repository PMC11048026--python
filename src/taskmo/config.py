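"""Experiment configuration: YAML-backed, schema-validated, fully seeded.

A config plus a master seed uniquely determines every artifact an
experiment writes.  The master seed is expanded into named sub-seeds
(dataset, splits, per-observer training) through ``numpy.random
.SeedSequence`` so stages are independently reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .synthetic import BackgroundSpec, PixelGrid, SignalSpecSKE, SignalSpecSKS

__all__ = ["ExperimentConfig", "load_config", "subseed"]


class GridSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rows: int = 64
    n_cols: int = 64
    pixel_spacing: float = 0.7


class BackgroundSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["white", "correlated-gaussian", "lumpy"] = "correlated-gaussian"
    mean_level: float = -850.0
    noise_sd: float = Field(56.0, ge=0)
    spectrum_alpha: float = 0.0
    spectrum_cutoff: float = Field(0.35, gt=0)
    lump_count_mean: float = Field(20.0, ge=0)
    lump_width: float = Field(4.0, gt=0)
    lump_magnitude: float = 30.0


class SignalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    paradigm: Literal["SKE", "SKS"] = "SKE"
    amplitude: float = -60.0
    radius: float = Field(4.0, gt=0)  # SKE, mm
    exponent: float = Field(4.0, gt=0)  # SKE
    sigma_x: float = Field(5.0, gt=0)  # SKS, pixels
    sigma_y: float = Field(1.5, gt=0)  # SKS, pixels
    angle_set: list[float] = [0.0, 45.0, 90.0, 135.0]  # SKS, degrees


class TaskSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid: GridSection = GridSection()
    background: BackgroundSection = BackgroundSection()
    signal: SignalSection = SignalSection()
    n_pairs: int = Field(500, ge=1)
    #: paired insertion (shared backgrounds, generator-verification mode) vs
    #: independent backgrounds per image (the mode learning studies should use)
    paired: bool = False


class ObserverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: Literal["ho", "cnn", "slnn", "cdae-svm", "pca-svm"]
    depth: Optional[int] = None
    filters: Optional[int] = None
    latent_units: Optional[int] = None
    epochs: Optional[int] = None
    max_epochs: Optional[int] = None
    weight_decay: Optional[float] = None
    corruption_rate: Optional[float] = None
    ridge: Optional[float | Literal["auto"]] = None


class ProtocolSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    train_images: int = Field(600, ge=4)
    val_images: int = Field(400, ge=4)
    test_images: int = Field(400, ge=4)
    sizes: list[int] = [100, 200, 500]
    repeats: int = Field(3, ge=1)


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    task: TaskSection = TaskSection()
    observers: list[ObserverSection] = [ObserverSection(name="ho")]
    protocol: ProtocolSection = ProtocolSection()
    seed: int = 0
    output: str = "taskmo-run"

    # --- constructors for the domain objects ---------------------------------
    def grid(self) -> PixelGrid:
        g = self.task.grid
        return PixelGrid(g.n_rows, g.n_cols, g.pixel_spacing)

    def background_spec(self) -> BackgroundSpec:
        return BackgroundSpec(**self.task.background.model_dump())

    def signal_spec(self):
        s = self.task.signal
        if s.paradigm == "SKE":
            return SignalSpecSKE(amplitude=s.amplitude, radius=s.radius,
                                 exponent=s.exponent)
        return SignalSpecSKS(amplitude=s.amplitude, sigma_x=s.sigma_x,
                             sigma_y=s.sigma_y, angle_set=tuple(s.angle_set))


def load_config(path: str | Path, seed_override: int | None = None,
                out_override: str | None = None) -> ExperimentConfig:
    """Parse and validate a YAML experiment config with readable diagnostics."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = ExperimentConfig(**raw)
    except ValidationError as exc:
        offending = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"invalid experiment config {path}: {offending}") from exc
    if seed_override is not None:
        cfg = cfg.model_copy(update={"seed": seed_override})
    if out_override is not None:
        cfg = cfg.model_copy(update={"output": out_override})
    return cfg


_STAGES = ("dataset", "split", "train", "search", "curve")


def subseed(master: int, stage: str, extra: int = 0) -> int:
    """Deterministic named sub-seed below 2**31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown seed stage {stage!r}")
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx, extra]).generate_state(1)[0] % 2**31)
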