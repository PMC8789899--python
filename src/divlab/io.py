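"""Configuration loading and result serialisation.

Configs are flat YAML key-value files; command-line flags override file
values and anything unresolved falls back to documented defaults.  Every
run writes a JSON sidecar echoing the resolved configuration, master seed
and package version, from which the run can be regenerated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = ["ConfigError", "RunConfig", "load_config", "export_results", "write_sidecar"]


class ConfigError(ValueError):
    """A configuration key is unknown or has the wrong type."""


@dataclass
class RunConfig:
    """Resolved configuration of one run: subcommand, full parameter map,
    master seed and output path."""

    subcommand: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out: str | None = None
    scale: str = "desk"

    def as_dict(self) -> dict[str, Any]:
        from . import __version__

        return {
            "subcommand": self.subcommand,
            "params": self.params,
            "seed": self.seed,
            "out": self.out,
            "scale": self.scale,
            "version": __version__,
        }


def load_config(
    subcommand: str,
    defaults: Mapping[str, Any],
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
    seed: int = 0,
    out: str | None = None,
    scale: str = "desk",
) -> RunConfig:
    """Merge defaults < config file < explicit flag overrides.

    Unknown keys and type mismatches raise :class:`ConfigError` naming the
    offending key.
    """
    params = dict(defaults)

    def apply(source: Mapping[str, Any], origin: str) -> None:
        for key, value in source.items():
            if value is None:
                continue
            if key not in params:
                raise ConfigError(f"unknown configuration key {key!r} ({origin})")
            expected = type(params[key])
            if expected in (int, float) and isinstance(value, (int, float)):
                value = expected(value)
            elif not isinstance(value, expected):
                raise ConfigError(
                    f"key {key!r} ({origin}): expected {expected.__name__}, "
                    f"got {type(value).__name__}"
                )
            params[key] = value

    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat key-value mapping")
        apply(loaded, f"file {path}")
    if overrides:
        apply(overrides, "flag")
    return RunConfig(subcommand=subcommand, params=params, seed=seed, out=out, scale=scale)


def export_results(records: pd.DataFrame, fmt: str, path: str | Path) -> Path:
    """Write a results table as CSV (full float precision, stable column
    order) or JSON records; both round-trip through pandas losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        records.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        records.to_json(path, orient="records", double_precision=15, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    return path


def write_sidecar(config: RunConfig, path: str | Path) -> Path:
    """JSON sidecar recording the resolved config, seed and version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(config.as_dict(), indent=1, default=str) + "\n")
    return path
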