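"""Run configuration: nested sections, YAML round-trip, strict keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .evaluation import EvalProtocol
from .model import ModelSpec
from .preprocess import PreprocessConfig
from .simulate import SimulationConfig

_SECTIONS = {
    "simulation": SimulationConfig,
    "preprocess": PreprocessConfig,
    "model": ModelSpec,
    "evaluation": EvalProtocol,
}


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    evaluation: EvalProtocol = field(default_factory=EvalProtocol)
    seed: int = 0                # global seed, overrides section seeds
    out_dir: str = "sorsnet_run"

    def with_global_seed(self) -> "RunConfig":
        """Propagate the global seed into every seeded section."""
        return dataclasses.replace(
            self,
            simulation=dataclasses.replace(self.simulation, seed=self.seed),
            model=dataclasses.replace(self.model, seed=self.seed),
            evaluation=dataclasses.replace(self.evaluation, seed=self.seed),
        )


def _build_section(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown keys in section {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    # YAML lists -> the tuple/frozenset fields the dataclasses expect
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            target = {"ablation": frozenset}.get(f.name, tuple)
            kwargs[f.name] = target(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {name: _build_section(cls, data.get(name, {}))
              for name, cls in _SECTIONS.items()}
    return RunConfig(seed=int(data.get("seed", 0)),
                     out_dir=str(data.get("out_dir", "sorsnet_run")),
                     **kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, frozenset)):
            return [clean(v) for v in sorted(obj) if True] \
                if isinstance(obj, frozenset) else [clean(v) for v in obj]
        return obj

    data = {name: clean(getattr(config, name)) for name in _SECTIONS}
    data["seed"] = config.seed
    data["out_dir"] = config.out_dir
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
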