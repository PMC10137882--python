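"""Run configuration: defaults, file loading, CLI overrides, manifests.

One flat configuration object mirrors the optimizer and pipeline knobs.
Precedence is CLI override > config file > defaults; unknown keys and
out-of-range values are rejected by name.  Every run can be stamped
with its seed, a hash of the resolved configuration and the package
version, so artifacts written from the same RunConfig are reproducible
byte for byte (timestamps excluded by construction — none are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .obl import OblConfig
from .sar import SarConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key."""


@dataclass(frozen=True)
class RunConfig:
    # optimizer
    pop_size: int = 50
    se: float = 0.05
    mu_max: int = 15
    max_iters: int = 350
    eps: float = 0.0
    mutation_ratio_p: float = 0.5
    seed: int = 0
    # OBL / schedule
    obl_mode: str = "per_iteration"
    schedule_enabled: bool = True
    # pipeline
    n_thresholds: int = 2
    method: str = "otsu"
    algorithm: str = "msar"

    def sar_config(self, sense: str = "maximize", seed: int | None = None) -> SarConfig:
        return SarConfig(
            pop_size=self.pop_size,
            se=self.se,
            mu_max=self.mu_max,
            max_iters=self.max_iters,
            sense=sense,
            eps=self.eps,
            mutation_ratio_p=self.mutation_ratio_p,
            seed=self.seed if seed is None else seed,
        )

    def obl_config(self) -> OblConfig:
        return OblConfig(mode=self.obl_mode, schedule_enabled=self.schedule_enabled)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def manifest(self) -> dict:
        return {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "version": __version__,
        }


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _validate(key: str, value):
    if key not in _FIELDS:
        raise ConfigError(f"unknown configuration key: {key!r}")
    checks = {
        "pop_size": lambda v: v >= 2,
        "se": lambda v: 0.0 <= v <= 1.0,
        "mu_max": lambda v: v >= 1,
        "max_iters": lambda v: v >= 1,
        "eps": lambda v: v >= 0.0,
        "mutation_ratio_p": lambda v: 0.0 <= v <= 1.0,
        "n_thresholds": lambda v: 1 <= v <= 20,
        "method": lambda v: v in ("otsu", "fuzzy"),
        "algorithm": lambda v: v in ("sar", "msar"),
        "obl_mode": lambda v: v in ("per_iteration", "init_only", "disabled"),
    }
    if key in checks and not checks[key](value):
        raise ConfigError(f"configuration value out of range for key {key!r}: {value!r}")


def load_config(path: str | Path | None = None, **cli_overrides) -> RunConfig:
    """Merge defaults, an optional YAML/JSON file, and CLI overrides
    (``None`` overrides are ignored); validate every assignment."""
    merged: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        for k, v in data.items():
            _validate(k, v)
            merged[k] = v
    for k, v in cli_overrides.items():
        if v is None:
            continue
        _validate(k, v)
        merged[k] = v
    return RunConfig(**merged)
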