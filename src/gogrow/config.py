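"""Validated run configuration shared by the CLI and the library.

A configuration file (YAML or JSON) carries the flat core keys of one
simulation — lattice geometry, rates, switch parameters, initial condition,
run length, seed — plus optional ``sweep``, ``extinction`` and ``pde``
sections for the experiment pipelines.  Unknown keys are rejected and every
value is validated against the model invariants before any computation
starts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .lgca import LatticeConfig, ModelParams
from .switching import SwitchParams

__all__ = ["RunConfig", "load_config", "dump_config", "to_model_params"]

_CORE_DEFAULTS = {
    "width": 100,
    "height": 100,
    "K": 8,
    "b": 4,
    "r_b": 0.2,
    "r_d": 0.01,
    "radius": 10.0,
    "occupy_prob": 0.25,
    "n_steps": 1000,
    "record_every": 1,
    "seed": 0,
}
_REQUIRED = ("kappa", "theta")
_SECTIONS = {
    "sweep": {"kappa_grid", "theta_grid", "replicates", "n_steps", "occupy_prob"},
    "extinction": {"occupy_probs", "replicates", "n_steps"},
    "pde": {"D0", "form", "dx", "dt", "t_end", "nx", "boundary"},
}


@dataclass(frozen=True)
class RunConfig:
    kappa: float
    theta: float
    width: int = 100
    height: int = 100
    K: int = 8
    b: int = 4
    r_b: float = 0.2
    r_d: float = 0.01
    radius: float = 10.0
    occupy_prob: float = 0.25
    n_steps: int = 1000
    record_every: int = 1
    seed: int = 0
    sweep: Optional[dict] = None
    extinction: Optional[dict] = None
    pde: Optional[dict] = None


def _validate(cfg: RunConfig) -> RunConfig:
    # delegate to the domain types, which enforce their own invariants
    to_model_params(cfg)
    if cfg.radius < 0:
        raise ValueError("radius: must be >= 0")
    if not (0.0 <= cfg.occupy_prob <= 1.0):
        raise ValueError("occupy_prob: must lie in [0, 1]")
    if cfg.n_steps < 0:
        raise ValueError("n_steps: must be >= 0")
    if cfg.record_every < 1:
        raise ValueError("record_every: must be >= 1")
    return cfg


def _from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = set(_CORE_DEFAULTS) | set(_REQUIRED) | set(_SECTIONS)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _REQUIRED:
        if key not in raw:
            raise ValueError(f"{key}: required key missing")
    for name, allowed in _SECTIONS.items():
        section = raw.get(name)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ValueError(f"{name}: must be a mapping")
        extra = set(section) - allowed
        if extra:
            raise ValueError(f"{name}: unknown keys {sorted(extra)}")
    merged = {**_CORE_DEFAULTS, **raw}
    try:
        cfg = RunConfig(**merged)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValueError(str(exc)) from exc
    try:
        return _validate(cfg)
    except ValueError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    return _from_dict(raw if raw is not None else {})


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a RunConfig back to YAML; round-trips through load."""
    d = {k: v for k, v in dataclasses.asdict(cfg).items() if v is not None}
    text = yaml.safe_dump(d, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def to_model_params(cfg: RunConfig) -> ModelParams:
    """Build the validated simulation parameter object from a config."""
    try:
        switch = SwitchParams(kappa=float(cfg.kappa), theta=float(cfg.theta))
    except ValueError as exc:
        raise ValueError(f"theta/kappa: {exc}") from exc
    lattice = LatticeConfig(
        width=int(cfg.width), height=int(cfg.height), K=int(cfg.K), b=int(cfg.b)
    )
    return ModelParams(
        r_b=float(cfg.r_b),
        r_d=float(cfg.r_d),
        switch=switch,
        lattice=lattice,
        seed=int(cfg.seed),
    )


def manifest_json(payload: dict) -> str:
    """Stable JSON manifest (sorted keys, no timestamps) for replayability."""
    return json.dumps(payload, indent=2, sort_keys=True)
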