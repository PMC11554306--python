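"""Pipeline configuration: a single YAML with per-stage sections.

Defaults follow the analysis conventions used throughout the package:
3 cm hole proximity, 20% speed threshold, 5 cm/s minimum drop, lattice
L = 11, 20 cm near-target radius, 30 x 30 cm probe squares, 120 s probe
window, 10 randomized pieces, 10,000 null draws, and the 5-degree angular
S.D. significance cut.  Unknown keys are rejected so typos never silently
fall back to defaults; every pipeline run writes the resolved config
beside its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .simulate import SimConfig


@dataclass(frozen=True)
class ArenaConfig:
    radius_cm: float = 60.0
    holes_per_quadrant: int = 25
    min_spacing_cm: float = 8.0
    wall_margin_cm: float = 3.0
    hole_capture_radius_cm: float = 1.5
    seed: int = 1


@dataclass(frozen=True)
class DetectConfig:
    proximity_radius_cm: float = 3.0
    speed_fraction: float = 0.2
    min_drop_cm_s: float = 5.0
    smoothing_window: int = 5
    merge_window_s: float = 0.5


@dataclass(frozen=True)
class LatticeConfig:
    L: int = 11


@dataclass(frozen=True)
class TevConfig:
    n_draws: int = 10_000
    sd_threshold_deg: float = 5.0
    centered_null: bool = False
    near_radius_cm: float = 20.0
    seed: int = 0


@dataclass(frozen=True)
class ProbeConfig:
    window_s: float = 120.0
    square_half_width_cm: float = 15.0
    criterion_radius_cm: float = 5.0
    n_pieces: int = 10
    n_random_points: int = 1000


@dataclass(frozen=True)
class PathsConfig:
    layout: str = ""
    manifest: str = ""
    output_dir: str = "hfmaze_out"


@dataclass(frozen=True)
class PipelineConfig:
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    tev: TevConfig = field(default_factory=TevConfig)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    seed: int = 0
    make_figures: bool = True


_SECTIONS = {
    "arena": ArenaConfig,
    "sim": SimConfig,
    "detect": DetectConfig,
    "lattice": LatticeConfig,
    "tev": TevConfig,
    "probe": ProbeConfig,
    "paths": PathsConfig,
}


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_known = set(_SECTIONS) | {"seed", "make_figures"}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build(cls, section, name)
    for scalar in ("seed", "make_figures"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path) -> None:
    """Write the fully resolved configuration as YAML."""
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
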