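"""Run configuration: thresholds, seeds and stratification mode.

All filter thresholds default to the values used throughout the analysis
(1.5x background signal, 80% presence, 3-fold variation in 2 samples, 20%
missingness, 2-SD interaction filter in 2 co-cultures) but are plain config
fields, never hard-coded at call sites.  Unknown keys in a config file are
rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass(frozen=True)
class RunConfig:
    background_factor: float = 1.5
    presence: float = 0.8
    fold: float = 3.0
    min_samples: int = 2
    missing: float = 0.2
    sd_threshold: float = 2.0
    min_cocultures: int = 2
    interaction_filter_mode: str = "retain_extreme"
    stratification: str = "cluster"  # or "score_sign"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.background_factor > 0, "background_factor must be > 0"),
            (0 < self.presence <= 1, "presence must be in (0, 1]"),
            (self.fold > 1, "fold must be > 1"),
            (self.min_samples >= 1, "min_samples must be >= 1"),
            (0 <= self.missing < 1, "missing must be in [0, 1)"),
            (self.sd_threshold > 0, "sd_threshold must be > 0"),
            (self.min_cocultures >= 1, "min_cocultures must be >= 1"),
            (
                self.interaction_filter_mode in ("retain_extreme", "eliminate_within"),
                "interaction_filter_mode must be retain_extreme or eliminate_within",
            ),
            (
                self.stratification in ("cluster", "score_sign"),
                "stratification must be cluster or score_sign",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file, rejecting unknown keys; overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**data)
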