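"""Run configuration: a single YAML document with strict validation.

Defaults mirror the study conditions: dt = 0.25 day, mechanics re-solved
every 4 steps, influence tolerance eps_s = 0.1, 1000 bootstrap samples.
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["ScenarioConfig", "SolverConfig", "SAConfig", "RunConfig", "load_config"]


@dataclass
class ScenarioConfig:
    perfusion: str = "well"            # well | poor
    shape: tuple[int, int, int] = (16, 16, 16)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_radius_mm: float = 8.0
    peak_density_fraction: float = 0.6
    smooth_mm: float = 2.0
    noise_amplitude: float = 0.02
    seed: int = 0
    n0_path: str | None = None         # custom scenario: explicit volumes
    p_path: str | None = None


@dataclass
class SolverConfig:
    dt: float = 0.25                   # days
    mech_every: int = 4                # steps between mechanics solves


@dataclass
class SAConfig:
    n_samples: int = 128
    seed: int = 0
    eps_s: float = 0.1
    n_boot: int = 1000


@dataclass
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    regimen: str = "dox_cyc"
    solver: SolverConfig = field(default_factory=SolverConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    out_dir: str = "runs"

    def validate(self) -> "RunConfig":
        if self.solver.dt <= 0:
            raise ConfigError("solver.dt must be > 0")
        if self.solver.mech_every < 1:
            raise ConfigError("solver.mech_every must be >= 1")
        if not 0 < self.sa.eps_s < 1:
            raise ConfigError("sa.eps_s must lie in (0, 1)")
        if self.sa.n_samples < 2:
            raise ConfigError("sa.n_samples must be >= 2")
        if self.regimen not in ("dox_cyc", "ptx_cpt"):
            raise ConfigError(f"unknown regimen {self.regimen!r}")
        if self.scenario.perfusion not in ("well", "poor", "custom"):
            raise ConfigError("scenario.perfusion must be well, poor or custom")
        return self


def _build(cls, data: dict, path: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown config key '{path}{sorted(unknown)[0]}'")
    kwargs = {}
    for name, value in data.items():
        f = allowed[name]
        if isinstance(value, dict):
            kwargs[name] = _build(f.default_factory, value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; an empty file yields all
    defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    cfg = _build(RunConfig, data, "")
    return cfg.validate()


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Persist the resolved configuration next to a run's outputs."""
    from dataclasses import asdict

    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
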