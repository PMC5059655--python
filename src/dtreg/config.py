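"""Nested pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "PhantomConfig", "BootstrapConfig",
           "TrackingConfig", "RegistrationConfig", "MetricsConfig",
           "stage_seed"]


@dataclass
class PhantomConfig:
    grid_shape: tuple = (40, 40, 20)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    noise_sigma: float = 20.0
    max_disp: float = 4.0
    s0: float = 1000.0


@dataclass
class BootstrapConfig:
    multiplier: str = "rademacher"  # {"rademacher", "none"}
    score: str = "identity"  # {"zero", "identity", "square"}
    gamma: object = "auto"  # "auto" or numeric override
    seed: int | None = None


@dataclass
class TrackingConfig:
    step_size: float | None = None  # mm; None -> half min voxel
    fa_threshold: float = 0.15
    max_steps: int = 2000
    sphere_subdivisions: int = 3
    n_samples: int = 1500
    seed_fa_threshold: float = 0.25


@dataclass
class RegistrationConfig:
    metric: str = "cc"
    cc_radius: int = 2
    levels: int = 3
    iterations: tuple = (100, 70, 40)
    step: float = 0.25
    sigma_fluid: float = 3.0
    sigma_elastic: float = 1.0
    log_transform: bool = True
    density_smoothing: float = 1.0


@dataclass
class MetricsConfig:
    fa_wm_threshold: float = 0.2
    centered_cc: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "dtreg_out"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _build(cls, d, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for sec in ("phantom",):
            for k in ("grid_shape", "voxel_size"):
                d[sec][k] = list(d[sec][k])
        d["registration"]["iterations"] = list(d["registration"]["iterations"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _build(cls, d, path):
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ValueError(f"config section '{path or cls.__name__}' must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        where = path or "top level"
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for name, val in d.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type)
            and dataclasses.is_dataclass(f.default_factory)
        ):
            kwargs[name] = _build(f.default_factory, val, f"{path}.{name}" if path else name)
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global one."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)
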