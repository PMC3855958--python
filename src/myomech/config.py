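"""Structured simulation configuration: schema, validation, fixtures.

Configs are nested blocks (geometry / material / fibers / cellmodel /
stimulus / schedule / experiment / output).  TOML and JSON files are
accepted; unknown keys are rejected with the offending name.  An empty
file yields the full defaults: the reduced isometric cube experiment with
the shipped material table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .constitutive import MaterialParams
from .errors import ConfigError

__all__ = ["SimConfig", "load_config", "dump_config", "make_fixture",
           "FIXTURE_NAMES"]

FIXTURE_NAMES = ("cube8_400", "cube8_36", "cube1_4", "fiber_only")


@dataclass
class GeometryBlock:
    nx: int = 1
    ny: int = 1
    nz: int = 1
    L: float = 2.0                      # cube edge length (cm)

    def validate(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigError("geometry.n{x,y,z} must be >= 1")
        if not self.L > 0:
            raise ConfigError("geometry.L must be > 0")


@dataclass
class FiberBlock:
    n_fibers: int = 4
    elements_per_fiber: int = 16
    fiber_type: str = "fast"
    direction: tuple = (1.0, 0.0, 0.0)

    def validate(self):
        if self.n_fibers < 1 or self.elements_per_fiber < 1:
            raise ConfigError("fibers.n_fibers and elements_per_fiber "
                              "must be >= 1")
        if self.fiber_type not in ("slow", "fast"):
            raise ConfigError("fibers.fiber_type must be 'slow' or 'fast'")


@dataclass
class CellModelBlock:
    model: str = "reduced"
    params: dict = field(default_factory=dict)

    def validate(self):
        if self.model != "reduced":
            raise ConfigError(f"unknown cell model {self.model!r}")


@dataclass
class StimulusBlock:
    frequency_hz: float = 100.0
    amplitude: float = 700.0
    width: float = 0.5
    start: float = 0.0

    def validate(self):
        if not self.frequency_hz > 0:
            raise ConfigError("stimulus.frequency_hz must be > 0")
        if self.amplitude < 0 or not self.width > 0:
            raise ConfigError("stimulus pulse invalid")


@dataclass
class ScheduleBlock:
    dt_hsm: float = 0.001               # ms
    n_hsm_per_deq: int = 10
    n_deq_per_cmm: int = 50
    t_end: float = 100.0                # ms

    def validate(self):
        if not self.dt_hsm > 0 or not self.t_end >= 0:
            raise ConfigError("schedule.dt_hsm must be > 0 and t_end >= 0")
        if self.n_hsm_per_deq < 1 or self.n_deq_per_cmm < 1:
            raise ConfigError("schedule step ratios must be >= 1")


@dataclass
class ExperimentBlock:
    preset: str = "isometric"           # isometric | shortening | passive
    prestretch: float = 0.2
    speed_fraction: float = 0.0
    prestretch_steps: int = 4

    def validate(self):
        if self.preset not in ("isometric", "shortening", "passive"):
            raise ConfigError(f"unknown experiment preset {self.preset!r}")
        if not 0.0 <= self.speed_fraction <= 1.0:
            raise ConfigError("experiment.speed_fraction must be in [0,1]")
        if self.prestretch <= -1:
            raise ConfigError("experiment.prestretch must exceed -1")


@dataclass
class OutputBlock:
    outdir: str = "out"
    write_csv: bool = True
    write_vtu: bool = False

    def validate(self):
        pass


_BLOCKS = {
    "geometry": GeometryBlock,
    "material": MaterialParams,
    "fibers": FiberBlock,
    "cellmodel": CellModelBlock,
    "stimulus": StimulusBlock,
    "schedule": ScheduleBlock,
    "experiment": ExperimentBlock,
    "output": OutputBlock,
}


@dataclass
class SimConfig:
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    material: MaterialParams = field(default_factory=MaterialParams)
    fibers: FiberBlock = field(default_factory=FiberBlock)
    cellmodel: CellModelBlock = field(default_factory=CellModelBlock)
    stimulus: StimulusBlock = field(default_factory=StimulusBlock)
    schedule: ScheduleBlock = field(default_factory=ScheduleBlock)
    experiment: ExperimentBlock = field(default_factory=ExperimentBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    def validate(self) -> "SimConfig":
        for name in _BLOCKS:
            block = getattr(self, name)
            if hasattr(block, "validate"):
                block.validate()
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        blocks = {}
        for key, payload in data.items():
            if key not in _BLOCKS:
                raise ConfigError(f"unknown config section {key!r}")
            cls_b = _BLOCKS[key]
            names = {f.name for f in dataclasses.fields(cls_b) if f.init}
            unknown = set(payload) - names
            if unknown:
                raise ConfigError(
                    f"unknown key(s) {sorted(unknown)} in section {key!r}")
            payload = dict(payload)
            for k, v in payload.items():
                if isinstance(v, list):
                    payload[k] = tuple(v)
            blocks[key] = cls_b(**payload)
        return cls(**blocks).validate()

    def to_dict(self) -> dict:
        out = {}
        for name in _BLOCKS:
            d = dataclasses.asdict(getattr(self, name))
            d = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in d.items()
                 if not k.startswith("_") and k not in ("n_states", "names")}
            out[name] = d
        return out


def load_config(path) -> SimConfig:
    """Load and validate a TOML or JSON config file; empty file = defaults."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return SimConfig().validate()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import tomllib
        data = tomllib.loads(text)
    return SimConfig.from_dict(data)


def dump_config(cfg: SimConfig, path) -> Path:
    """Write the effective config as JSON (round-trips through load)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
                    + "\n")
    return path


def make_fixture(name: str) -> SimConfig:
    """Ready-to-run configurations for the shipped benchmark geometries."""
    if name == "cube8_400":
        cfg = SimConfig(
            geometry=GeometryBlock(nx=2, ny=2, nz=2, L=2.0),
            fibers=FiberBlock(n_fibers=400, elements_per_fiber=60))
    elif name == "cube8_36":
        cfg = SimConfig(
            geometry=GeometryBlock(nx=2, ny=2, nz=2, L=2.0),
            fibers=FiberBlock(n_fibers=36, elements_per_fiber=60))
    elif name == "cube1_4":
        cfg = SimConfig(
            geometry=GeometryBlock(nx=1, ny=1, nz=1, L=2.0),
            fibers=FiberBlock(n_fibers=4, elements_per_fiber=16))
    elif name == "fiber_only":
        cfg = SimConfig(
            geometry=GeometryBlock(nx=1, ny=1, nz=1, L=2.0),
            fibers=FiberBlock(n_fibers=1, elements_per_fiber=60),
            experiment=ExperimentBlock(preset="isometric", prestretch=0.0))
    else:
        raise ConfigError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return cfg.validate()
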