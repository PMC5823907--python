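"""Parsing and validation of scenario configuration files.

Configuration files (YAML or JSON) mirror the :class:`ScenarioConfig` field
names.  Validation injects the literature defaults, normalizes units
(concentrations mM, lengths m, times s) and rejects unknown keys so typos
fail loudly rather than silently running the default.
"""

from __future__ import annotations

import json

import yaml

from .engine import ScenarioConfig

__all__ = ["validate_config", "load_config", "dump_config"]


def validate_config(raw: dict | None) -> ScenarioConfig:
    """Build a fully-resolved :class:`ScenarioConfig` from an override map."""
    raw = dict(raw or {})
    known = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "inoculum" in raw:
        ino = raw["inoculum"]
        if not (hasattr(ino, "__len__") and len(ino) == 2):
            raise ValueError("inoculum must be a (aerobes, anaerobes) pair")
        raw["inoculum"] = (int(ino[0]), int(ino[1]))
    return ScenarioConfig(**raw)  # dataclass __post_init__ does the checks


def load_config(path: str) -> ScenarioConfig:
    with open(path) as fh:
        text = fh.read()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return validate_config(raw)


def dump_config(config: ScenarioConfig, path: str | None = None) -> str:
    text = json.dumps(config.to_dict(), indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
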