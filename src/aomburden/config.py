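"""Run configuration: one YAML file driving the whole pipeline.

Exactly one of ``inputs`` (paths to child/visit CSVs) or ``simulate`` (a
synthetic-cohort parameter block) must be present. All randomness flows from
the single top-level ``seed``; modules never self-seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields, is_dataclass
from pathlib import Path

import yaml

from .cases import CaseDefinition
from .episodes import EpisodeConfig
from .recurrence import RecurrenceConfig
from .simulate import SimulationParams
from .trends import ITSSpec


@dataclass(frozen=True)
class InputPaths:
    children: str
    visits: str
    exclusion_list: str | None = None


@dataclass
class RunConfig:
    out_dir: str = "aomburden_out"
    seed: int = 0
    study_start: str = "2010-01-01"
    study_end: str = "2017-12-31"
    #: "full" keeps every child's person-time in the denominator;
    #: "eligible" removes excluded children's person-time as well.
    denominator: str = "full"
    log_level: str = "INFO"
    inputs: InputPaths | None = None
    simulate: SimulationParams | None = None
    case: CaseDefinition = field(default_factory=CaseDefinition)
    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    recurrence: RecurrenceConfig = field(default_factory=RecurrenceConfig)
    its: ITSSpec = field(default_factory=ITSSpec)

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' must be configured")
        if self.denominator not in ("full", "eligible"):
            raise ValueError(f"unknown denominator mode: {self.denominator!r}")


_SECTION_TYPES = {
    "inputs": InputPaths,
    "simulate": SimulationParams,
    "case": CaseDefinition,
    "episode": EpisodeConfig,
    "recurrence": RecurrenceConfig,
    "its": ITSSpec,
}

_TUPLE_FIELDS = {"icd9_prefixes", "text_patterns", "covariates"}


def _build_section(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "exclusion_list":
            v = frozenset(v)
        elif f.name == "text_patterns":
            v = tuple((str(m), str(p)) for m, p in v)
        elif f.name in _TUPLE_FIELDS:
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if value is not None:
                kwargs[key] = _build_section(_SECTION_TYPES[key], dict(value))
        else:
            kwargs[key] = value
    unknown = set(kwargs) - {f.name for f in fields(RunConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


def load_config(path, overrides: dict[str, str] | None = None) -> RunConfig:
    """Load a YAML config, applying dotted-key ``--set`` overrides first."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    for dotted, raw in (overrides or {}).items():
        _set_dotted(data, dotted, yaml.safe_load(raw))
    return config_from_dict(data)


def _set_dotted(data: dict, dotted: str, value):
    parts = dotted.split(".")
    node = data
    for p in parts[:-1]:
        node = node.setdefault(p, {})
        if not isinstance(node, dict):
            raise ValueError(f"cannot override non-mapping key {p!r} in {dotted!r}")
    node[parts[-1]] = value


def config_echo(config: RunConfig) -> dict:
    """JSON-serializable echo of the effective configuration."""

    def conv(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (frozenset, set, tuple)):
            return sorted(conv(v) for v in obj) if isinstance(obj, (frozenset, set)) else [conv(v) for v in obj]
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return conv(config)
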