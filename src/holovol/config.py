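"""Pipeline configuration: YAML schema, validation, and derived reports."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .wave import InvalidConfiguration, OpticalConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "report_fov"]


class ConfigError(ValueError):
    """Raised for malformed configuration files."""


@dataclass
class AcquisitionConfig:
    n_heights: int = 6
    z_start: float = 700.0
    z_step: float = 20.0
    noise_sigma: float = 0.0

    def z_list(self) -> list[float]:
        return [self.z_start + i * self.z_step for i in range(self.n_heights)]


@dataclass
class RecoveryConfig:
    tol: float = 1e-4
    max_iter: int = 50
    init_phase: str = "zero"
    refine_z: bool = False


@dataclass
class DeconvolutionConfig:
    method: str = "gold"
    beta: float = 0.001
    n_iter: int = 20
    mode: str = "amplitude"
    source_kind: str = "point-blocker"
    z_start: float = 660.0
    z_stop: float = 780.0
    z_step: float = 5.0

    def z_values(self) -> list[float]:
        out, z = [], self.z_start
        while z <= self.z_stop + 1e-9:
            out.append(round(z, 9))
            z += self.z_step
        return out


@dataclass
class SceneConfig:
    kind: str = "beads"
    n: int = 8
    diameter: float = 1.0
    z_planes: list[float] = field(default_factory=lambda: [700.0, 760.0])
    bar_widths: list[float] = field(default_factory=lambda: [3.0, 2.0])
    shape: list[int] = field(default_factory=lambda: [256, 256])


@dataclass
class PipelineConfig:
    """Everything a full simulate -> PSR -> phase -> deconvolve run needs.

    Defaults follow the reference acquisition: 532 nm illumination,
    1.67 um detector pixels, a 6 x 6 sub-pixel grid, six detector heights
    20 um apart, and deconvolution with beta = 0.001.
    """

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    recovery: RecoveryConfig = field(default_factory=RecoveryConfig)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0
    output_dir: str = "holovol_out"


_SECTIONS = {
    "optical": OpticalConfig,
    "acquisition": AcquisitionConfig,
    "recovery": RecoveryConfig,
    "deconvolution": DeconvolutionConfig,
    "scene": SceneConfig,
}
_SCALARS = {"seed": int, "output_dir": str}


def _build_section(cls, payload: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    for key in payload:
        if key not in allowed:
            raise ConfigError(f"unknown key '{where}.{key}'; allowed: {sorted(allowed)}")
    try:
        return cls(**payload)
    except (TypeError, InvalidConfiguration, ValueError) as exc:
        raise ConfigError(f"invalid section '{where}': {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    An empty file yields all defaults; unknown keys are rejected with
    their location.
    """
    raw = Path(path).read_text()
    payload = yaml.safe_load(raw)
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError(f"config root must be a mapping, got {type(payload).__name__}")
    kwargs = {}
    for key, value in payload.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key in _SCALARS:
            kwargs[key] = _SCALARS[key](value)
        else:
            raise ConfigError(
                f"unknown top-level key '{key}'; allowed: "
                f"{sorted([*_SECTIONS, *_SCALARS])}"
            )
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def report_fov(config: PipelineConfig | OpticalConfig, sensor_dims: tuple[int, int]) -> float:
    """Field-of-view area in mm^2, rounded to 2 decimals.

    The 10.7-megapixel sensor (3872 x 2764 pixels at 1.67 um) covers
    29.85 mm^2.
    """
    optical = config.optical if isinstance(config, PipelineConfig) else config
    return round(optical.fov_mm2(sensor_dims), 2)
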