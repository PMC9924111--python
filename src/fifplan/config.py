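"""Run configuration: one YAML schema covering phantom, beams, dose engine,
FIF settings, normalization and the optimizer objective.

An empty file yields the standard clinical defaults (hotspot at 107% of Rx,
1 cm^3 minimum, 3% decrement, six subfields, 5 MU floor, 99.9% coverage,
30 Gy / 10 fractions).  Unknown keys and out-of-range values are rejected
before any computation, naming the offending key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .dose import EngineParams
from .fif import FIFConfig
from .optimize import NormalizationSpec, WeightObjective
from .phantom import (
    PhantomSpec,
    default_phantom_spec,
    flat_phantom_spec,
    mild_phantom_spec,
    stress_phantom_spec,
)

PHANTOM_PRESETS = {
    "default": default_phantom_spec,
    "stress": stress_phantom_spec,
    "mild": mild_phantom_spec,
    "flat": flat_phantom_spec,
}


class ConfigError(ValueError):
    pass


@dataclass
class BeamConfig:
    gantry_pair: tuple[float, float] = (90.0, 270.0)
    sad_mm: float = 1000.0
    isocenter: tuple[float, float, float] | None = None  # None: brain centroid
    margin_mm: float = 7.0
    leaf_width_mm: float = 5.0
    bev_spacing_mm: float = 2.0
    bev_half_extent_mm: float = 160.0

    def validate(self) -> None:
        if self.sad_mm <= 0:
            raise ConfigError("beams.sad_mm must be positive")
        if abs(((self.gantry_pair[1] - self.gantry_pair[0]) % 360.0) - 180.0) > 1e-6:
            raise ConfigError("beams.gantry_pair must be 180 degrees apart")
        if self.leaf_width_mm <= 0 or self.bev_spacing_mm <= 0:
            raise ConfigError("beams.leaf_width_mm and beams.bev_spacing_mm must be positive")


@dataclass
class PhantomConfig:
    preset: str = "default"
    density_path: str | None = None  # load instead of generating
    masks_dir: str | None = None
    overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.preset not in PHANTOM_PRESETS:
            raise ConfigError(
                f"phantom.preset must be one of {sorted(PHANTOM_PRESETS)}"
            )
        if (self.density_path is None) != (self.masks_dir is None):
            raise ConfigError(
                "phantom.density_path and phantom.masks_dir must be given together"
            )
        valid = {f.name for f in dataclasses.fields(PhantomSpec)}
        for k in self.overrides:
            if k not in valid:
                raise ConfigError(f"phantom.overrides.{k} is not a phantom parameter")

    def spec(self) -> PhantomSpec:
        overrides = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in self.overrides.items()
        }
        return PHANTOM_PRESETS[self.preset](**overrides)


@dataclass
class NormalizationConfig:
    mode: str = "volume"  # "point" is named in clinical configs but not implemented
    coverage: float = 0.999
    dose_level: float = 1.0

    def validate(self) -> None:
        if self.mode not in ("volume", "point"):
            raise ConfigError("normalization.mode must be 'volume' or 'point'")
        if not 0 < self.coverage <= 1:
            raise ConfigError("normalization.coverage must be in (0, 1]")
        if self.dose_level <= 0:
            raise ConfigError("normalization.dose_level must be positive")

    def spec(self) -> NormalizationSpec:
        if self.mode == "point":
            raise NotImplementedError("point normalization is not implemented; use mode 'volume'")
        return NormalizationSpec(self.coverage, self.dose_level)


@dataclass
class ObjectiveConfig:
    overdose_weight: float = 1.0
    underdose_weight: float = 1.0
    voxel_stride: int = 1

    def validate(self) -> None:
        if self.overdose_weight < 0 or self.underdose_weight < 0:
            raise ConfigError("objective penalty weights must be non-negative")
        if self.voxel_stride < 1:
            raise ConfigError("objective.voxel_stride must be >= 1")


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    beams: BeamConfig = field(default_factory=BeamConfig)
    engine: EngineParams = field(default_factory=EngineParams)
    fif: FIFConfig = field(default_factory=FIFConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    mu_per_weight: float = 100.0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.phantom.validate()
        self.beams.validate()
        self.engine.validate()
        self.fif.validate()
        self.normalization.validate()
        self.objective.validate()
        if self.mu_per_weight <= 0:
            raise ConfigError("mu_per_weight must be positive")

    def weight_objective(self) -> WeightObjective:
        return WeightObjective(
            rx_gy=self.fif.rx_gy,
            overdose_weight=self.objective.overdose_weight,
            underdose_weight=self.objective.underdose_weight,
            min_weight=self.fif.min_mu / self.mu_per_weight,
            voxel_stride=self.objective.voxel_stride,
        )


def _build(cls, data: dict, prefix: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key {prefix}.{sorted(unknown)[0]}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {prefix}: {exc}") from exc


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    sections = {
        "phantom": PhantomConfig,
        "beams": BeamConfig,
        "engine": EngineParams,
        "fif": FIFConfig,
        "normalization": NormalizationConfig,
        "objective": ObjectiveConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        sub = data.pop(name, {}) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {name} must be a mapping")
        kwargs[name] = _build(cls, sub, name)
    for scalar in ("mu_per_weight", "log_level"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ConfigError(f"unknown key {sorted(data)[0]}")
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _listify(dataclasses.asdict(cfg))


def load_config(path: str | None) -> RunConfig:
    """Load and validate a YAML run configuration (None/empty -> defaults)."""
    if path is None:
        return config_from_dict({})
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
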