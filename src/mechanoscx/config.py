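"""Configuration files: loading, validation, run manifests.

YAML throughout (JSON is a YAML subset and is accepted unchanged).
Validation aggregates every problem into one :class:`ConfigError` whose
message names each offending field, instead of failing on the first.
"""

from __future__ import annotations

import dataclasses
import datetime
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .calibrate import ConstraintSet
from .model import Condition, PressureProtocol
from .params import ParameterSet, load_parameters

__all__ = [
    "ConfigError", "RunConfig",
    "load_conditions", "default_conditions",
    "load_constraints", "default_constraints",
    "validate_config", "write_manifest",
]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " +
                         "\n  - ".join(self.errors))


def _load_yaml(path: str | Path) -> Mapping:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError([f"{path}: expected a mapping at top level"])
    return raw


def load_conditions(path: str | Path) -> list[Condition]:
    """Read a list of treatment conditions from YAML."""
    raw = _load_yaml(path)
    entries = raw.get("conditions", raw)
    if not isinstance(entries, list):
        raise ConfigError([f"{path}: 'conditions' must be a list"])
    errors, out = [], []
    for i, e in enumerate(entries):
        label = e.get("name", f"#{i}") if isinstance(e, Mapping) else f"#{i}"
        if not isinstance(e, Mapping):
            errors.append(f"condition {label}: not a mapping")
            continue
        try:
            segs = tuple(tuple(s) for s in e.get("pressure_segments", ()))
            out.append(Condition(
                name=str(e["name"]),
                mgf_initial=e.get("mgf_initial", 0),
                protocol=PressureProtocol(segs),
                inhibition=e.get("inhibition", 1.0)))
        except (KeyError, TypeError, ValueError) as err:
            errors.append(f"condition {label}: {err}")
    if errors:
        raise ConfigError(errors)
    return out


def load_constraints(path: str | Path) -> ConstraintSet:
    raw = _load_yaml(path)
    entries = raw.get("constraints", raw)
    fields = {f.name for f in dataclasses.fields(ConstraintSet)}
    unknown = set(entries) - fields
    errors = [f"unknown constraint field {k!r}" for k in sorted(unknown)]
    if errors:
        raise ConfigError(errors)
    kwargs = dict(entries)
    if "window" in kwargs:
        kwargs["window"] = tuple(kwargs["window"])
    try:
        return ConstraintSet(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError([str(err)]) from err


def _packaged(name: str):
    return importlib.resources.as_file(
        importlib.resources.files("mechanoscx.data").joinpath(name))


def default_conditions() -> list[Condition]:
    with _packaged("conditions_default.yaml") as p:
        return load_conditions(p)


def default_constraints() -> ConstraintSet:
    with _packaged("constraints_default.yaml") as p:
        return load_constraints(p)


@dataclass(frozen=True)
class RunConfig:
    """Normalised pipeline run configuration.

    Seed and replicate count are mandatory so every recorded artifact is
    regenerable; file paths may be omitted to use the shipped defaults.
    """

    seed: int
    reps: int
    out: Path
    horizon: float = 48.0
    grid_step: float = 0.5
    mode: str = "ssa"
    params_file: Path | None = None
    conditions_file: Path | None = None
    constraints_file: Path | None = None
    options: dict = field(default_factory=dict)

    def load(self) -> tuple[ParameterSet, list[Condition], ConstraintSet]:
        from .params import default_parameters
        params = load_parameters(self.params_file) if self.params_file \
            else default_parameters()
        conditions = load_conditions(self.conditions_file) \
            if self.conditions_file else default_conditions()
        constraints = load_constraints(self.constraints_file) \
            if self.constraints_file else default_constraints()
        return params, conditions, constraints


def validate_config(source: str | Path | Mapping) -> RunConfig:
    """Normalise and range-check a run configuration (path or mapping)."""
    raw = dict(_load_yaml(source)) if not isinstance(source, Mapping) \
        else dict(source)
    errors = []

    def need(key, kind, check, what):
        v = raw.get(key)
        if v is None:
            errors.append(f"{key}: required")
            return None
        try:
            v = kind(v)
        except (TypeError, ValueError):
            errors.append(f"{key}: expected {kind.__name__}, got {v!r}")
            return None
        if not check(v):
            errors.append(f"{key}: {what}, got {v!r}")
            return None
        return v

    seed = need("seed", int, lambda v: 0 <= v < 2 ** 31,
                "must be in [0, 2^31)")
    reps = need("reps", int, lambda v: v >= 1, "must be >= 1")
    horizon = raw.get("horizon", 48.0)
    grid_step = raw.get("grid_step", 0.5)
    if not (isinstance(horizon, (int, float)) and horizon > 0):
        errors.append(f"horizon: must be a positive number, got {horizon!r}")
    if not (isinstance(grid_step, (int, float)) and 0 < grid_step <= horizon):
        errors.append(f"grid_step: must lie in (0, horizon], got {grid_step!r}")
    mode = raw.get("mode", "ssa")
    if mode not in ("ssa", "ode"):
        errors.append(f"mode: must be 'ssa' or 'ode', got {mode!r}")
    out = raw.get("out")
    if not out:
        errors.append("out: required output directory")

    paths = {}
    for key in ("params_file", "conditions_file", "constraints_file"):
        p = raw.get(key)
        if p is not None:
            p = Path(p)
            if not p.is_file():
                errors.append(f"{key}: no such file {p}")
            paths[key] = p

    known = {"seed", "reps", "horizon", "grid_step", "mode", "out",
             "params_file", "conditions_file", "constraints_file", "options"}
    options = dict(raw.get("options") or {})
    for key in sorted(set(raw) - known):
        errors.append(f"unknown key {key!r} (put subcommand options under "
                      f"'options')")
    if errors:
        raise ConfigError(errors)
    cfg = RunConfig(seed=seed, reps=reps, out=Path(out),
                    horizon=float(horizon), grid_step=float(grid_step),
                    mode=mode, options=options, **paths)
    # cross-checks that need the referenced files
    try:
        _, conditions, constraints = cfg.load()
    except ConfigError:
        raise
    except (ValueError, OSError) as err:
        raise ConfigError([str(err)]) from err
    post = []
    if constraints.horizon > cfg.horizon:
        post.append(f"constraints horizon {constraints.horizon} h exceeds "
                    f"run horizon {cfg.horizon} h")
    if constraints.window[1] > cfg.horizon:
        post.append(f"constraint window {constraints.window} outside the "
                    f"run horizon {cfg.horizon} h")
    if post:
        raise ConfigError(post)
    return cfg


def write_manifest(out_dir: Path, subcommand: str, config: Mapping,
                   artifacts: Sequence[str]) -> Path:
    """Record how a run's artifacts were produced (config echo, seed,
    package version, timestamp)."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dict(config).items()},
        "artifacts": list(artifacts),
        "package": "mechanoscx",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
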