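"""YAML configuration loading with full validation.

Unspecified keys fall back to the published rate-table defaults; unknown keys
are rejected with the list of valid names so typos cannot silently revert a
rate to its default.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .params import (
    BistableParams,
    SignalEffectParams,
    SignalParams,
    SimConfig,
    TristableParams,
)

__all__ = ["load_config", "dump_config", "config_to_dict"]

_SECTIONS = {
    "stem": BistableParams,
    "progenitor": TristableParams,
    "signal": SignalParams,
    "signal_effect": SignalEffectParams,
}


def _build_section(cls, data, where: str):
    if not isinstance(data, dict):
        raise ValueError(f"section {where!r} must be a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where!r}; "
                         f"valid keys: {sorted(names)}")
    return cls(**data)


def load_config(path) -> SimConfig:
    """Parse a YAML config file into a :class:`SimConfig`.

    An empty file yields the pure defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    top_names = {f.name for f in fields(SimConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}; "
                         f"valid keys: {sorted(top_names)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)


def dump_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
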