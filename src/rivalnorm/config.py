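"""Configuration loading and bit-stable output writing.

Configuration files are JSON-compatible structured text (JSON or YAML); every
field defaults to the model's documented value, so an empty file yields the
default model.  Unknown keys are rejected by name (typo safety).  Outputs are
CSVs with fixed column order and 6-significant-digit floats, plus a
JSON-compatible sidecar echoing the effective configuration and seed, so a
(config, seed) pair determines every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import pandas as pd
import yaml

from .dynamics import DynamicsParams, ModelParams
from .normalization import NoiseParams
from .stimulus import ConditionSpec, GeometrySpec, PoolAccounting

__all__ = ["RunConfig", "ConfigError", "load_config", "write_outputs", "get_logger"]

FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Configuration parse or validation failure, naming the offending key."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: condition + model + campaign blocks."""

    condition: ConditionSpec = field(default_factory=ConditionSpec)
    model: ModelParams = field(default_factory=ModelParams)
    n_runs: int = 100
    seed: int = 0
    verbosity: str = "info"

    def echo(self) -> Dict[str, Any]:
        """JSON-compatible dump of the effective configuration."""

        def as_dict(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: as_dict(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, Mapping):
                return {str(k): as_dict(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [as_dict(v) for v in obj]
            return obj

        return {
            "condition": as_dict(self.condition),
            "model": as_dict(self.model),
            "n_runs": self.n_runs,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }


def _build(cls, data: Mapping[str, Any], context: str, **overrides):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(field_names)}"
        )
    kwargs = dict(data)
    kwargs.update(overrides)
    # JSON/YAML lists -> tuples where the dataclass expects tuples
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def load_config(path: Optional[str] = None, overrides: Optional[Mapping[str, Any]] = None) -> RunConfig:
    """Load and validate a run configuration (None or empty file -> defaults)."""
    raw: Dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ConfigError(f"top level of {path} must be a mapping")
        raw = parsed
    if overrides:
        raw = {**raw, **overrides}

    known = {"condition", "geometry", "noise", "dynamics", "accounting", "campaign", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(known)}")

    geometry = _build(GeometrySpec, raw.get("geometry", {}), "geometry block")
    cond_data = dict(raw.get("condition", {}))
    if "disk_assignment" in cond_data:
        cond_data["disk_assignment"] = {
            tuple(k.split("/")): v for k, v in cond_data["disk_assignment"].items()
        }
    condition = _build(ConditionSpec, cond_data, "condition block", geometry=geometry)
    noise = _build(NoiseParams, raw.get("noise", {}), "noise block")
    dynamics = _build(DynamicsParams, raw.get("dynamics", {}), "dynamics block")
    accounting = _build(PoolAccounting, raw.get("accounting", {}), "accounting block")

    campaign = dict(raw.get("campaign", {}))
    unknown = set(campaign) - {"n_runs", "seed"}
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in campaign block")

    config = RunConfig(
        condition=condition,
        model=ModelParams(noise=noise, dynamics=dynamics, accounting=accounting),
        n_runs=int(campaign.get("n_runs", 100)),
        seed=int(campaign.get("seed", 0)),
        verbosity=str(raw.get("verbosity", "info")),
    )
    try:
        config.condition.validate()
        config.model.accounting.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return config


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str,
    sidecar: Optional[Mapping[str, Any]] = None,
) -> Dict[str, Path]:
    """Write tables as deterministic CSVs plus a JSON sidecar.

    Floats are formatted with 6 significant digits; identical inputs produce
    identical bytes.  Returns the paths written, keyed by table name.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        for name, table in tables.items():
            p = out / f"{name}.csv"
            table.to_csv(p, index=False, float_format=FLOAT_FORMAT)
            paths[name] = p
        if sidecar is not None:
            p = out / "run_metadata.json"
            p.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
            paths["run_metadata"] = p
        return paths
    except OSError as exc:
        raise OSError(f"cannot write outputs under {out}: {exc}") from exc


def get_logger(verbosity: str = "info") -> logging.Logger:
    """Logger writing to standard error, never mixed into data streams."""
    logger = logging.getLogger("rivalnorm")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, verbosity.upper(), logging.INFO))
    return logger
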