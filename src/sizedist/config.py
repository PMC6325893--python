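"""Run configuration and provenance records for the command-line interface.

Defaults reproduce the standard screen settings: n=1000 resampled cells,
parametric bootstrap B=999, alpha=0.01, top 50 deviants and 5% size tails.
Configuration can come from a YAML file mirroring the CLI flags; flags
override file values.  Every output table gets a JSON provenance record
(`<output>.provenance.json`) from which the run can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """An invalid configuration field, named in the message."""


@dataclass(frozen=True)
class RunConfig:
    input: str | None = None
    output: str | None = None
    n: int = 1000
    jitter: bool = False
    bootstrap: int = 999
    seed: int = 42
    wild_type: tuple[str, ...] = ()
    shape: float | None = None
    rate: float | None = None
    top: int = 50
    tail: float = 0.05
    alpha: float = 0.01
    min_size: float | None = None

    def validate(self) -> "RunConfig":
        if self.n < 1:
            raise ConfigError("n: resample size must be >= 1")
        if self.bootstrap < 99:
            raise ConfigError("bootstrap: B must be >= 99 for a calibrated p-value")
        if not 0 < self.tail < 0.5:
            raise ConfigError("tail: tail fraction must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: significance level must be in (0, 1)")
        if self.top < 1:
            raise ConfigError("top: top-k must be >= 1")
        if (self.shape is None) != (self.rate is None):
            raise ConfigError("shape/rate: a fixed null needs both shape and rate")
        return self


def load_config(path: str | Path) -> dict:
    """Read a YAML key-value config file mirroring the CLI flags."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if "wild_type" in data and isinstance(data["wild_type"], list):
        data["wild_type"] = tuple(data["wild_type"])
    return data


def merge_config(file_values: dict, flag_values: dict) -> RunConfig:
    """Build a RunConfig from file values overridden by explicit flags."""
    merged = dict(file_values)
    merged.update({k: v for k, v in flag_values.items() if v is not None})
    return RunConfig(**merged).validate()


def write_provenance(output_path: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a JSON provenance record next to an output file."""
    from . import __version__

    record = {
        "package": "sizedist",
        "version": __version__,
        "config": dataclasses.asdict(config),
        **(extra or {}),
    }
    prov = Path(str(output_path) + ".provenance.json")
    prov.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return prov
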