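"""Pipeline configuration: YAML-backed, validated, hashable.

Defaults follow the published pipeline settings wherever one exists (patch
size 30, 120/40 foreground/background pixels per tagged section, Adam
1e-4/0.9/0.999, batch 256, sliding window 30 at step 10, periodogram band
600-1620 min, 50% binarization threshold, 9 hidden nodes, 70% training
fraction, cubic expansion).  Validation uses pydantic models; the CLI loads
a YAML file into :class:`PipelineConfig` and lets flags override fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class PathsConfig(BaseModel):
    out_dir: str = "runs/fixture"
    images_dir: str | None = None  # default: <out_dir>/frames
    annotations: str | None = None
    ocean_csv: str | None = None


class ImagingConfig(BaseModel):
    clahe_clip_limit: float = Field(2.0, gt=0)
    clahe_tile_grid: tuple[int, int] = (8, 8)
    hue_bands: list[tuple[float, float]] = [(0.0, 25.0), (340.0, 360.0)]
    sat_range: tuple[float, float] = (0.18, 1.0)
    val_range: tuple[float, float] = (0.12, 1.0)
    median_kernel: int = Field(3, ge=3)


class PatchConfig(BaseModel):
    size: int = Field(30, ge=4)
    n_fg: int = Field(120, ge=1)
    n_bg: int = Field(40, ge=1)


class CnnConfig(BaseModel):
    reduced: bool = True  # narrow variant for CPU runs; False = full-width model
    learning_rate: float = Field(1e-4, gt=0)
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = Field(256, ge=1)
    epochs: int = Field(100, ge=1)
    augment: bool = True
    shift_frac: float = Field(0.1, ge=0, lt=0.5)


class WindowConfig(BaseModel):
    window: int = Field(30, ge=4)
    step: int = Field(10, ge=1)


class ChronoConfig(BaseModel):
    period_min: float = Field(600.0, gt=0)
    period_max: float = Field(1620.0, gt=0)
    grid_step_min: float = Field(1.0, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    bin_minutes: int = Field(60, ge=1)
    bin_offset_minutes: int = 0


class MlfnConfig(BaseModel):
    threshold_pct: float = 50.0
    nodes: int = Field(9, ge=1)
    train_frac: float = Field(0.70, gt=0, lt=1)
    max_degree: int = Field(3, ge=1)
    max_iter: int = Field(500, ge=1)
    k: int | None = None  # None = choose by CV RMS curve


class SimulateConfig(BaseModel):
    n_frames: int = Field(72, ge=1)
    frame_size: int = Field(256, ge=64)
    n_hours: int = Field(720, ge=48)
    rhythm_peak_hour: float = 21.5
    rhythm_amplitude: float = 30.0
    noise_sd: float = 5.0


class PipelineConfig(BaseModel):
    paths: PathsConfig = PathsConfig()
    imaging: ImagingConfig = ImagingConfig()
    patches: PatchConfig = PatchConfig()
    cnn: CnnConfig = CnnConfig()
    segmentation: WindowConfig = WindowConfig()
    chronostats: ChronoConfig = ChronoConfig()
    mlfn: MlfnConfig = MlfnConfig()
    simulate: SimulateConfig = SimulateConfig()
    seed: int = 0


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load YAML into a validated PipelineConfig; missing file -> defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration (for run records)."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
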