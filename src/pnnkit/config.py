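"""Pipeline configuration: YAML in, validated dataclasses out.

Only keys that exist in the schema are accepted; every field left at its
default is reported by :func:`defaulted_fields` so the run log can state
the full effective configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path as FsPath

import yaml

from .geometry import ParameterError

__all__ = ["PipelineConfig", "load_config", "dump_config", "defaulted_fields"]


@dataclass
class GeometryConfig:
    lateral_spacing: float = 0.04
    axial_spacing: float = 0.125
    n_slices: int = 52
    psf_sigma_lateral: float = 0.064
    psf_sigma_axial: float = 0.127


@dataclass
class DetectorConfig:
    diameter_um: float | None = None
    min_separation_um: float = 0.4
    threshold_k: float = 4.0


@dataclass
class TopologyConfig:
    base_threshold: float = 0.7
    r95_start: float = 0.7
    r95_step: float = 0.05
    r95_max: float = 3.0


@dataclass
class PunctaConfig:
    threshold: str | float = "otsu"
    min_size_px: int = 3
    max_size_px: int | None = None
    projection: bool = True
    ball_radius_px: float = 50.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    force_gate: str | None = None      # parametric | nonparametric | None
    p_adjust: str = "holm"


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_animals_per_group: int = 4
    n_sections: int = 3
    n_pnns_per_section: int = 5
    subregion: str = "DG"
    node_count: float = 100.0
    shell_radius: float = 4.0
    snr: float = 10.0
    animal_cv: float = 0.1
    render: str = "images"             # images | summary
    sections: bool = False
    # flat effect spec: "factor:level:param" -> multiplier
    effects: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def effect_spec(self) -> dict:
        out: dict = {}
        for key, mult in self.simulate.effects.items():
            parts = str(key).split(":")
            if len(parts) != 3:
                raise ParameterError(
                    f"effect key {key!r} must be 'factor:level:param'")
            factor, level, param = parts
            out.setdefault((factor, level), {})[param] = float(mult)
        return out


def _build(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ParameterError(f"config section {path or cls.__name__} must be "
                             "a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ParameterError(
            f"unknown config key(s) {sorted(unknown)} in section "
            f"{path or 'root'}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.default_factory, type)
                and dataclasses.is_dataclass(f.default_factory)):
            kwargs[name] = _build(f.default_factory, data[name],
                                  f"{path}.{name}" if path else name)
        else:
            kwargs[name] = data[name]
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file; ``overrides`` are applied on top."""
    data: dict = {}
    if path is not None:
        text = FsPath(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        for key, value in overrides.items():
            data[key] = value
    return _build(PipelineConfig, data)


def dump_config(config: PipelineConfig, path) -> None:
    FsPath(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def defaulted_fields(config: PipelineConfig) -> list[str]:
    """Dotted names of every field still at its default value."""
    out: list[str] = []

    def walk(obj, default_obj, prefix=""):
        for f in fields(obj):
            v, d = getattr(obj, f.name), getattr(default_obj, f.name)
            name = f"{prefix}{f.name}"
            if dataclasses.is_dataclass(v):
                walk(v, d, name + ".")
            elif v == d:
                out.append(name)

    walk(config, PipelineConfig())
    return out
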