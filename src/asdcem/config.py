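"""Model configuration: parameter blocks, YAML round-tripping, overrides.

The default-constructed :class:`ModelConfig` carries the published basecase
parameter set.  Scenario and sensitivity machinery mutates configurations
only through :meth:`ModelConfig.with_overrides`, which takes dotted keys
(e.g. ``intervention.cost_infusion``) and returns a deep copy, so every
analysis is a pure config transform.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .analyses import BIAParams
from .costs import CostParams
from .engine import EngineConfig
from .intervention import InterventionParams, NormalParams
from .life_tables import MortalityParams
from .natural_history import CohortParams, GrowthBand, NaturalHistoryParams
from .qol import QolParams

__all__ = ["ModelConfig", "ConfigError"]


class ConfigError(KeyError):
    """Raised for unknown configuration keys."""


@dataclass
class ModelConfig:
    mortality: MortalityParams = field(default_factory=MortalityParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    intervention: InterventionParams = field(default_factory=InterventionParams)
    qol: QolParams = field(default_factory=QolParams)
    costs: CostParams = field(default_factory=CostParams)
    engine: EngineConfig = field(default_factory=EngineConfig)
    bia: BIAParams = field(default_factory=BIAParams)
    lifetable_path: Optional[str] = None

    # -- construction -------------------------------------------------------

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        cfg = cls()
        for key, value in data.items():
            if key == "lifetable_path":
                cfg.lifetable_path = value
                continue
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config section {key!r}")
            section = getattr(cfg, key)
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            _update_dataclass(section, value, prefix=key)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = _serialize(value)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- overrides -----------------------------------------------------------

    def with_overrides(self, overrides: dict[str, Any]) -> "ModelConfig":
        """Deep copy with dotted-key overrides applied and validated."""
        cfg = copy.deepcopy(self)
        for dotted, value in overrides.items():
            _set_dotted(cfg, dotted, value)
        return cfg

    def config_hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _serialize(value: Any) -> Any:
    if is_dataclass(value) and not isinstance(value, type):
        return {f.name: _serialize(getattr(value, f.name)) for f in fields(value)}
    if isinstance(value, list):
        return [_serialize(v) for v in value]
    if isinstance(value, dict):
        return {k: _serialize(v) for k, v in value.items()}
    return value


def _update_dataclass(obj: Any, data: dict[str, Any], prefix: str) -> None:
    names = {f.name for f in fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown config key {prefix}.{key}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, prefix=f"{prefix}.{key}")
        elif key == "monthly_change":
            bands = [GrowthBand(**b) if isinstance(b, dict) else b for b in value]
            setattr(obj, key, bands)
        elif isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            merged.update(value)
            setattr(obj, key, merged)
        else:
            setattr(obj, key, value)
    if hasattr(obj, "__post_init__"):
        obj.__post_init__()


def _set_dotted(cfg: ModelConfig, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    obj: Any = cfg
    for i, part in enumerate(parts[:-1]):
        if is_dataclass(obj) and not isinstance(obj, type):
            if part not in {f.name for f in fields(obj)}:
                raise ConfigError(f"unknown config key {dotted!r}")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            if part not in obj:
                raise ConfigError(f"unknown config key {dotted!r}")
            obj = obj[part]
        else:
            raise ConfigError(f"cannot descend into {'.'.join(parts[:i + 1])!r}")
    leaf = parts[-1]
    if is_dataclass(obj) and not isinstance(obj, type):
        if leaf not in {f.name for f in fields(obj)}:
            raise ConfigError(f"unknown config key {dotted!r}")
        setattr(obj, leaf, value)
        if hasattr(obj, "__post_init__"):
            obj.__post_init__()
    elif isinstance(obj, dict):
        if leaf not in obj:
            raise ConfigError(f"unknown config key {dotted!r}")
        obj[leaf] = value
    else:
        raise ConfigError(f"cannot set {dotted!r}")
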