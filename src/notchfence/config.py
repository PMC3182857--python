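"""YAML configuration for experiments.

The schema mirrors :class:`notchfence.experiments.ExperimentConfig`: the
top level holds the experiment choice, seed and run length; nested mappings
``initial_condition``, ``mechanics``, ``cycle`` and ``thresholds`` override
individual dataclass fields.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Dict, Mapping, Optional, Type

import yaml

from .cycle import CycleParams
from .dynamics import TopologyThresholds
from .experiments import ExperimentConfig
from .mechanics import MechanicsParams
from .mesh import InitialConditionSpec

__all__ = ["load_config", "config_from_dict", "config_to_dict", "dump_config"]

_SECTIONS: Dict[str, Type] = {
    "initial_condition": InitialConditionSpec,
    "mechanics": MechanicsParams,
    "cycle": CycleParams,
    "thresholds": TopologyThresholds,
}
_TOP_KEYS = {
    "experiment",
    "mutant_variant",
    "run_cycles",
    "seed",
    "sample_every",
    "identity_mode",
    "stop_on_breach",
} | set(_SECTIONS)


def _build_section(cls: Type, data: Mapping[str, Any], section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = _coerce_tuple(value)
        coerced[key] = value
    return cls(**coerced)


def _coerce_tuple(value):
    return tuple(_coerce_tuple(v) if isinstance(v, list) else v for v in value)


def config_from_dict(data: Mapping[str, Any]) -> ExperimentConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: Dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], value or {}, key)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def config_to_dict(config: ExperimentConfig) -> Dict[str, Any]:
    """Full parameter dump (for reproducibility headers of every output)."""
    out: Dict[str, Any] = {
        "experiment": config.experiment,
        "mutant_variant": config.mutant_variant,
        "run_cycles": config.run_cycles,
        "seed": config.seed,
        "sample_every": config.sample_every,
        "identity_mode": config.identity_mode,
        "stop_on_breach": config.stop_on_breach,
    }
    for name, _ in _SECTIONS.items():
        out[name] = dataclasses.asdict(getattr(config, name))
    return out


def dump_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
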