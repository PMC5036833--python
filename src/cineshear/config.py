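"""Run configuration: a YAML-serialisable description of a full analysis."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .acquisition import AcquisitionSpec
from .errors import ConfigurationError
from .geometry import VesselGeometry
from .segmentation import SnakeParams
from .sweep import TABLE1_GRID
from .waveform import WaveformSpec, carotid_waveform

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a sweep run."""

    # geometry
    radius: float = 2.8
    profile: str = "circular"
    apex_offset: tuple[float, float] = (0.0, 0.0)
    viscosity: float = 1.0e-3
    density: float = 1000.0
    # waveform
    period: float = 1.0
    mean_flow: float = 2.7
    peak_flow: float = 9.1
    n_harmonics: int = 8
    # acquisition
    venc: float = 100.0
    snr: float | None = None
    supersampling: int = 8
    field_of_view: float = 12.8
    # grid: "table1" or explicit [[no, mm, ms], ...]
    grid: str | list = "table1"
    # segmentation
    segmentation: str = "per-measurement"
    snake_elasticity: float = 0.05
    snake_stiffness: float = 0.1
    snake_external_weight: float = 1.0
    snake_step: float = 0.1
    # WSS
    wss_offsets: tuple[float, float] = (1.5, 3.0)
    # run
    seed: int = 0
    output_dir: str = "results"

    def geometry_obj(self) -> VesselGeometry:
        return VesselGeometry(
            radius=self.radius,
            profile=self.profile,
            apex_offset=tuple(self.apex_offset),
            viscosity=self.viscosity,
            density=self.density,
        )

    def waveform_obj(self) -> WaveformSpec:
        return carotid_waveform(
            mean=self.mean_flow, peak=self.peak_flow, period=self.period, n_harmonics=self.n_harmonics
        )

    def acquisition_template(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            pixel_spacing=1.0,
            frame_duration=100.0,
            venc=self.venc,
            snr=self.snr,
            supersampling=self.supersampling,
            field_of_view=self.field_of_view,
        )

    def snake_params(self) -> SnakeParams:
        return SnakeParams(
            elasticity=self.snake_elasticity,
            stiffness=self.snake_stiffness,
            external_weight=self.snake_external_weight,
            step=self.snake_step,
        )

    def grid_pairs(self) -> tuple[tuple[int, float, float], ...]:
        if self.grid == "table1":
            return TABLE1_GRID
        pairs = tuple((int(n), float(s), float(t)) for n, s, t in self.grid)
        numbers = [p[0] for p in pairs]
        if len(set(numbers)) != len(numbers):
            raise ConfigurationError("grid entries must be unique by measure number")
        return pairs

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        blob = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if cfg.radius <= 0 or cfg.viscosity <= 0 or cfg.venc <= 0:
        raise ConfigurationError("physical parameters must be positive")
    return cfg


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(asdict(cfg)), sort_keys=True))
    return path
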