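"""Run configuration: structured files (JSON or YAML) validated into a
scenario specification.

Unknown keys are hard errors rather than being ignored — a typo in a rate
constant name must not silently fall back to a default.  Every default
that is filled in is logged (to standard error via the package logger).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .model1 import CompetitionState, Model1Params, Model1State
from .model2 import Model2Params, Model2State
from .scenarios import PRESET_NAMES, ScenarioSpec, preset
from .affinity_grid import build_grid, build_kernel

log = logging.getLogger("abdyn")

__all__ = ["RunConfig", "load_config", "save_config", "build_spec"]

_TOP_KEYS = {"scenario", "overrides", "output_dir", "rtol", "atol", "log_level"}
_OVERRIDE_KEYS = {"t_end", "n_points", "p_values", "params", "initial_state",
                  "model"}
_PARAM_KEYS = {"k1", "k2", "k_minus2", "k3", "k4", "k5", "k6", "p"}
_STATE_KEYS = {"x", "y", "z"}
_LOG_LEVELS = {"DEBUG", "INFO", "WARNING", "ERROR"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    ``overrides`` mirrors ScenarioSpec fields (t_end, n_points, p_values,
    params.<rate>, initial_state.<component>); only known keys are
    accepted.
    """

    scenario: str = "clonal_deletion"
    overrides: dict = dataclasses.field(default_factory=dict)
    output_dir: str | None = None
    rtol: float | None = None
    atol: float | None = None
    log_level: str = "INFO"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


def _check_number(value, path: str, *, minimum=None, maximum=None,
                  strict_min=False) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigurationError(
            f"{path}: expected a number, got {type(value).__name__}"
        )
    v = float(value)
    if minimum is not None:
        if strict_min and v <= minimum:
            raise ConfigurationError(f"{path}: must be > {minimum}, got {v}")
        if not strict_min and v < minimum:
            raise ConfigurationError(f"{path}: must be >= {minimum}, got {v}")
    if maximum is not None and v > maximum:
        raise ConfigurationError(f"{path}: must be <= {maximum}, got {v}")
    return v


def _validate_overrides(ov: dict) -> None:
    _require(isinstance(ov, dict), "overrides: expected a mapping")
    unknown = set(ov) - _OVERRIDE_KEYS
    _require(not unknown, f"overrides: unknown key(s) {sorted(unknown)}")
    if "t_end" in ov:
        _check_number(ov["t_end"], "overrides.t_end", minimum=0.0,
                      strict_min=True)
    if "n_points" in ov:
        _require(isinstance(ov["n_points"], int) and ov["n_points"] >= 2,
                 "overrides.n_points: expected an integer >= 2")
    if "p_values" in ov:
        _require(isinstance(ov["p_values"], (list, tuple)) and ov["p_values"],
                 "overrides.p_values: expected a non-empty list")
        for j, p in enumerate(ov["p_values"]):
            _check_number(p, f"overrides.p_values[{j}]", minimum=0.0,
                          maximum=1.0)
    if "params" in ov:
        _require(isinstance(ov["params"], dict),
                 "overrides.params: expected a mapping")
        unknown = set(ov["params"]) - _PARAM_KEYS
        _require(not unknown,
                 f"overrides.params: unknown rate(s) {sorted(unknown)}")
        for name, val in ov["params"].items():
            if name == "p":
                _check_number(val, "overrides.params.p", minimum=0.0,
                              maximum=1.0)
            elif name == "k2":
                _check_number(val, "overrides.params.k2", minimum=0.0,
                              strict_min=True)
            else:
                _check_number(val, f"overrides.params.{name}", minimum=0.0)
    if "initial_state" in ov:
        st = ov["initial_state"]
        _require(isinstance(st, dict), "overrides.initial_state: expected a "
                 "mapping")
        unknown = set(st) - _STATE_KEYS
        _require(not unknown,
                 f"overrides.initial_state: unknown key(s) {sorted(unknown)}")
        for name, val in st.items():
            if isinstance(val, (list, tuple)):
                for j, v in enumerate(val):
                    _check_number(v, f"overrides.initial_state.{name}[{j}]",
                                  minimum=0.0)
            else:
                _check_number(val, f"overrides.initial_state.{name}",
                              minimum=0.0)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON or YAML config file (format picked by
    extension: .json vs .yaml/.yml)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raise ConfigurationError(
            f"unrecognized config extension {path.suffix!r} "
            "(expected .json, .yaml or .yml)"
        )
    if raw is None:
        raw = {}
    _require(isinstance(raw, dict), "config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    _require(not unknown, f"unknown config key(s) {sorted(unknown)}")

    defaults = RunConfig()
    for fld in dataclasses.fields(RunConfig):
        if fld.name not in raw:
            log.info("config: using default %s=%r", fld.name,
                     getattr(defaults, fld.name))

    scenario = raw.get("scenario", defaults.scenario)
    _require(isinstance(scenario, str), "scenario: expected a string")
    _require(scenario in PRESET_NAMES or scenario == "custom",
             f"scenario: {scenario!r} not in {PRESET_NAMES + ('custom',)}")
    overrides = raw.get("overrides", {})
    _validate_overrides(overrides)
    rtol = raw.get("rtol")
    atol = raw.get("atol")
    if rtol is not None:
        rtol = _check_number(rtol, "rtol", minimum=0.0, strict_min=True)
    if atol is not None:
        atol = _check_number(atol, "atol", minimum=0.0, strict_min=True)
    log_level = raw.get("log_level", defaults.log_level)
    _require(log_level in _LOG_LEVELS,
             f"log_level: {log_level!r} not in {sorted(_LOG_LEVELS)}")
    output_dir = raw.get("output_dir")
    if output_dir is not None:
        _require(isinstance(output_dir, str), "output_dir: expected a string")
    return RunConfig(
        scenario=scenario,
        overrides=overrides,
        output_dir=output_dir,
        rtol=rtol,
        atol=atol,
        log_level=log_level,
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to JSON or YAML (format by extension).

    ``load_config(save_config(...))`` round-trips field-identically.
    """
    path = Path(path)
    payload = {k: v for k, v in dataclasses.asdict(config).items()
               if v is not None and v != {}}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        raise ConfigurationError(
            f"unrecognized config extension {path.suffix!r}"
        )


def _apply_param_overrides(params, updates: dict):
    if isinstance(params, list):
        return [_apply_param_overrides(p, updates) for p in params]
    bad = [k for k in updates
           if not hasattr(params, k)]
    if bad:
        raise ConfigurationError(
            f"overrides.params: {bad} not valid for {type(params).__name__}"
        )
    return dataclasses.replace(params, **updates)


def _apply_state_overrides(state, updates: dict):
    converted = {}
    for name, val in updates.items():
        current = getattr(state, name)
        if isinstance(current, np.ndarray):
            arr = np.asarray(val, dtype=float)
            if arr.shape != current.shape:
                raise ConfigurationError(
                    f"overrides.initial_state.{name}: expected "
                    f"{current.shape[0]} values, got {arr.size}"
                )
            converted[name] = arr
        else:
            if isinstance(val, (list, tuple)):
                raise ConfigurationError(
                    f"overrides.initial_state.{name}: expected a scalar"
                )
            converted[name] = float(val)
    return dataclasses.replace(state, **converted)


def _custom_spec(overrides: dict) -> ScenarioSpec:
    """Build a scenario from scratch (scenario: custom).

    Requires overrides.model, overrides.params, overrides.initial_state
    and overrides.t_end.  Model 2 customs use the default 9-class grid.
    """
    for key in ("model", "params", "initial_state", "t_end"):
        _require(key in overrides, f"custom scenario requires overrides.{key}")
    model = overrides["model"]
    _require(model in ScenarioSpec._MODELS,
             f"overrides.model: {model!r} not in {ScenarioSpec._MODELS}")
    pr = dict(overrides["params"])
    st = overrides["initial_state"]
    if model.startswith("model1"):
        _require("k2" in pr, "custom model1 scenario requires params.k2")
        pr.pop("p", None)
        params = Model1Params(**pr)
        if model == "model1_competition":
            state = CompetitionState(
                x=np.asarray(st.get("x", []), dtype=float),
                y=np.asarray(st.get("y", []), dtype=float),
                z=float(st.get("z", 0.0)),
            )
            members = {"competition": [params] * state.m}
        else:
            state = Model1State(x=float(st.get("x", 0.0)),
                                y=float(st.get("y", 0.0)),
                                z=float(st.get("z", 0.0)))
            members = {"antibody": params}
    else:
        grid = build_grid()
        kernel = build_kernel(grid)
        p_values = tuple(overrides.get("p_values", (pr.pop("p", 0.0),)))
        base = {k: v for k, v in pr.items()
                if k in ("k3", "k4", "k6", "k1", "k5")}
        members = {
            f"p={p:g}": Model2Params(grid=grid, kernel=kernel, p=p, **base)
            for p in p_values
        }
        state = Model2State(
            x=np.asarray(st.get("x", np.zeros(grid.n)), dtype=float),
            y=np.asarray(st.get("y", np.zeros(grid.n)), dtype=float),
            z=float(st.get("z", 0.0)),
        )
    return ScenarioSpec(
        name="custom",
        model=model,
        members=members,
        initial_state=state,
        t_end=float(overrides["t_end"]),
        n_points=int(overrides.get("n_points", 500)),
        p_values=tuple(overrides["p_values"]) if "p_values" in overrides
        else None,
    )


def build_spec(config: RunConfig) -> ScenarioSpec:
    """Turn a validated RunConfig into a concrete ScenarioSpec."""
    if config.scenario == "custom":
        spec = _custom_spec(config.overrides)
    else:
        spec = preset(config.scenario)
        ov = config.overrides
        _require("model" not in ov,
                 "overrides.model is only valid with scenario: custom")
        changes: dict = {}
        if "t_end" in ov:
            changes["t_end"] = float(ov["t_end"])
        if "n_points" in ov:
            changes["n_points"] = int(ov["n_points"])
        members = dict(spec.members)
        if "p_values" in ov:
            _require(spec.model.startswith("model2"),
                     "overrides.p_values only applies to repertoire scenarios")
            base = spec.params
            p_values = tuple(float(p) for p in ov["p_values"])
            members = {
                f"p={p:g}": dataclasses.replace(base, p=p) for p in p_values
            }
            changes["p_values"] = p_values
        if "params" in ov:
            members = {
                label: _apply_param_overrides(prm, ov["params"])
                for label, prm in members.items()
            }
        changes["members"] = members
        if "initial_state" in ov:
            changes["initial_state"] = _apply_state_overrides(
                spec.initial_state, ov["initial_state"]
            )
        spec = dataclasses.replace(spec, **changes)
    if config.rtol is not None:
        spec = dataclasses.replace(spec, rtol=config.rtol)
    if config.atol is not None:
        spec = dataclasses.replace(spec, atol=config.atol)
    return spec
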