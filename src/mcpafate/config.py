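"""Run configuration loading, validation, and provenance stamping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .params import (
    DepthProfileParams,
    LGCPParams,
    ReactionParams,
    TransportParams,
    VanGenuchtenLayer,
    default_layers,
    parameter_registry,
)

_KNOWN_KEYS = {
    "scenario", "precipitation", "preset", "n_realizations", "base_seed",
    "t_end_days", "layers", "transport", "reaction", "profile", "lgcp",
    "mesh", "tolerances", "outputs",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated scenario run specification with registry defaults."""

    scenario: str = "HOM"
    precipitation: str = "CLR"
    preset: str = "desk"
    n_realizations: int | None = None
    base_seed: int = 20240
    t_end_days: float | None = None
    layers: list[VanGenuchtenLayer] = field(default_factory=default_layers)
    transport: TransportParams = field(default_factory=TransportParams)
    reaction: ReactionParams = field(default_factory=ReactionParams)
    profile: DepthProfileParams = field(default_factory=DepthProfileParams)
    lgcp: LGCPParams | None = None
    mesh: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _build_layers(spec) -> list[VanGenuchtenLayer]:
    try:
        return [VanGenuchtenLayer(**row) for row in spec]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"layers: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown top-level keys are rejected; omitted blocks fall back to the
    reference parameter registry defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("scenario", "precipitation", "preset", "n_realizations",
                "base_seed", "t_end_days", "mesh", "tolerances", "outputs"):
        if key in raw:
            kwargs[key] = raw[key]
    if "layers" in raw:
        kwargs["layers"] = _build_layers(raw["layers"])
    for key, cls in (("transport", TransportParams), ("reaction", ReactionParams),
                     ("profile", DepthProfileParams), ("lgcp", LGCPParams)):
        if key in raw:
            try:
                kwargs[key] = cls(**raw[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: {exc}") from exc
    cfg = RunConfig(**kwargs)
    if cfg.scenario not in ("HOM", "LOW", "HIGH", "EXTR"):
        raise ConfigError(f"scenario: unknown label {cfg.scenario!r}")
    if cfg.precipitation not in ("CLR", "HRE"):
        raise ConfigError(f"precipitation: unknown label {cfg.precipitation!r}")
    return cfg


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def provenance_stamp(cfg: RunConfig, seeds: list[int | None],
                     extra: dict | None = None) -> dict:
    """Self-describing metadata block embedded in every run output.

    The parameter hash covers the full configuration (layers included), so a
    run is reproducible from its stamp alone.
    """
    payload = {
        "config": _jsonable(asdict(cfg)),
        "seeds": seeds,
        "registry": parameter_registry(),
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    stamp = {
        "code_version": __version__,
        "parameter_hash": digest,
        "seeds": seeds,
        "tolerances": cfg.tolerances or {"head_increment_m": 1e-6,
                                         "mass_balance_rel": 1e-3},
    }
    if extra:
        stamp.update(extra)
    return stamp
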