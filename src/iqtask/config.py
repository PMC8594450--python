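"""Experiment configuration: YAML-backed, validated, fully serializable.

Defaults encode the standard study conditions: Table-style CLB texture
parameters on a 128x128 field, per-task noise levels (sigma_p=0.013,
sigma_g=0.35 for the Rayleigh task; 1e-4 and 1e-3 for the MC task), the
decade lambda grid 1e-9..1e-4, and a 64x64 central evaluation crop.

The intensity scale of the CLB model and the Rayleigh signal height are free
parameters of the simulation; they are calibrated once against the published
ensemble-fidelity numbers (LR-vs-HR ensemble MSE of each task, and the
MSE/PSNR pair that fixes the PSNR peak) and frozen here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from iqtask.imaging import DegradationSpec, NoiseSpec
from iqtask.phantoms import CLBParams, MCClusterSpec, RayleighSignalSpec

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "RAYLEIGH_CLB_AMPLITUDE",
    "RAYLEIGH_SIGNAL_AMPLITUDE",
    "MC_CLB_AMPLITUDE",
    "MC_PSNR_PEAK",
]

# Calibrated intensity constants (see docs/methods.md).
RAYLEIGH_CLB_AMPLITUDE = 2.6784
RAYLEIGH_SIGNAL_AMPLITUDE = 8.0
MC_CLB_AMPLITUDE = 1.7225
MC_PSNR_PEAK = 128.51492

DEFAULT_LAMBDA_GRID = [1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CLBSection(_Section):
    mean_clusters: float = Field(150.0, gt=0)
    mean_blobs_per_cluster: float = Field(20.0, gt=0)
    half_axis_x: float = Field(5.0, gt=0)
    half_axis_y: float = Field(2.0, gt=0)
    alpha: float = Field(2.1, gt=0)
    beta: float = Field(0.5, gt=0)
    cluster_spread: float = Field(12.0, gt=0)
    field_size: int = Field(128, gt=0)
    amplitude: Optional[float] = Field(None, gt=0)  # None -> per-task calibrated value


class NoiseSection(_Section):
    poisson_scale: Optional[float] = Field(None, ge=0)
    gaussian_std: Optional[float] = Field(None, ge=0)
    poisson_rate: float = Field(10.0, gt=0)


class DegradationSection(_Section):
    blur_sigma: float = Field(1.5, gt=0)
    downsample_factor: Optional[int] = Field(None, ge=1)
    upsample_back: Optional[bool] = None


class RayleighSignalSection(_Section):
    signal_length: int = Field(7, ge=3)
    blur_sigma: float = Field(1.375, gt=0)
    amplitude: float = Field(RAYLEIGH_SIGNAL_AMPLITUDE, gt=0)


class MCSection(_Section):
    canvas_size: int = Field(200, ge=128)
    n_mcs_range: tuple[int, int] = (5, 12)
    cluster_radius: float = Field(40.0, gt=0)
    mc_size_range: tuple[int, int] = (2, 6)
    contrast_range: tuple[float, float] = (0.05, 0.06)
    rotation_range: tuple[float, float] = (0.0, 360.0)


class TrainingSection(_Section):
    batch_size: int = Field(16, ge=1)
    learning_rate: float = Field(5e-4, gt=0)
    max_epochs: int = Field(20, ge=1)
    semionline_noise: bool = False
    augment_flips: bool = False


class SweepSection(_Section):
    signal_lengths: list[int] = [5, 6, 7, 8, 9]
    depths: list[int] = [2, 4, 6]
    block_grid: list[int] = [2, 6]
    n_train_grid: list[int] = [200, 600]
    n_fit_per_class: int = Field(300, ge=2)
    n_test_per_class: int = Field(300, ge=2)


class ExperimentConfig(_Section):
    task: Literal["rayleigh", "mc"] = "rayleigh"
    master_seed: int = 0
    n_per_class: int = Field(100, ge=1)
    crop: int = Field(64, ge=2)
    peak: float | Literal["auto"] = MC_PSNR_PEAK
    lambda_grid: list[float] = DEFAULT_LAMBDA_GRID
    output_dir: str = "runs"
    clb: CLBSection = CLBSection()
    noise: NoiseSection = NoiseSection()
    degradation: DegradationSection = DegradationSection()
    signal: RayleighSignalSection = RayleighSignalSection()
    mc: MCSection = MCSection()
    training: TrainingSection = TrainingSection()
    sweep: SweepSection = SweepSection()

    @model_validator(mode="after")
    def _fill_task_defaults(self) -> "ExperimentConfig":
        ray = self.task == "rayleigh"
        if self.clb.amplitude is None:
            self.clb.amplitude = RAYLEIGH_CLB_AMPLITUDE if ray else MC_CLB_AMPLITUDE
        if self.noise.poisson_scale is None:
            self.noise.poisson_scale = 0.013 if ray else 0.0001
        if self.noise.gaussian_std is None:
            self.noise.gaussian_std = 0.35 if ray else 0.001
        if self.degradation.downsample_factor is None:
            self.degradation.downsample_factor = 1 if ray else 2
        if self.degradation.upsample_back is None:
            self.degradation.upsample_back = not ray
        return self

    # ---- domain-object views -------------------------------------------

    def clb_params(self) -> CLBParams:
        c = self.clb
        return CLBParams(
            c.mean_clusters, c.mean_blobs_per_cluster, c.half_axis_x, c.half_axis_y,
            c.alpha, c.beta, c.cluster_spread, c.field_size, c.amplitude,
        )

    def noise_spec(self) -> NoiseSpec:
        n = self.noise
        return NoiseSpec(n.poisson_scale, n.gaussian_std, n.poisson_rate)

    def degradation_spec(self) -> DegradationSpec:
        d = self.degradation
        return DegradationSpec(d.blur_sigma, d.downsample_factor, d.upsample_back, self.task)

    def signal_spec(self) -> RayleighSignalSpec:
        s = self.signal
        return RayleighSignalSpec(s.signal_length, s.blur_sigma, s.amplitude)

    def mc_spec(self) -> MCClusterSpec:
        m = self.mc
        return MCClusterSpec(
            m.canvas_size, tuple(m.n_mcs_range), m.cluster_radius,
            tuple(m.mc_size_range), tuple(m.contrast_range), tuple(m.rotation_range),
        )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML config; missing keys take defaults, unknown keys fail."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if overrides:
        data.update(overrides)
    try:
        return ExperimentConfig(**data)
    except ValidationError as err:
        bad = ", ".join(".".join(str(p) for p in e["loc"]) for e in err.errors())
        raise ConfigError(f"invalid config ({bad}):\n{err}") from err


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
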