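"""Run configuration: schema, validation, defaults and provenance.

A run is described by a two-level mapping (YAML on disk) with blocks

* ``scenario``  — preset name or explicit landscape knobs
* ``model``     — overrides of the organismal/ecological constants
* ``evolution`` — EvoRunConfig fields
* ``tolerances``— equilibrium solver settings
* ``output``    — output directory

Unknown keys are rejected with their full path; loading resolves every
default and records, per parameter, whether it came from the user or from
the calibrated defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .core import Model1Params
from .evolution import EvoRunConfig
from .scenarios import ORGANISMAL_DEFAULTS, generate_scenario

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config", "resolve_config"]

_PRESETS = {
    "fig2-null": dict(scenario="two_resource", k_ell_null=True),
    "fig2-evo": dict(scenario="two_resource", k_ell_null=False),
    "fig3": dict(scenario="ten_resource", k_ell_null=False),
}

_MODEL_KEYS = set(ORGANISMAL_DEFAULTS) | {"n", "D", "theta1", "F_max_each"}
_SCENARIO_KEYS = {"kind", "preset", "eta0", "ell0", "inoculum", "seeds", "n",
                  "D", "theta1", "F_max_each"}
_EVOLUTION_KEYS = {f.name for f in dataclasses.fields(EvoRunConfig)}
_TOLERANCE_KEYS = {"eq_tol", "newton_tol", "t_max_eco"}
_TOP_KEYS = {"scenario", "model", "evolution", "tolerances", "output"}


class ConfigError(ValueError):
    """Schema violation, reported with the offending key path."""


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    scenario: dict
    model: dict
    evolution: EvoRunConfig
    output: Optional[str] = None
    provenance: dict = field(default_factory=dict)

    def build(self):
        """Instantiate (Model1Params, initial CommunityState) for this run."""
        knobs = {k: v for k, v in self.scenario.items() if k != "kind"}
        knobs.update(self.model)
        return generate_scenario(self.scenario["kind"], **knobs)

    def to_mapping(self) -> dict:
        evo = dataclasses.asdict(self.evolution)
        return {
            "scenario": dict(self.scenario),
            "model": dict(self.model),
            "evolution": evo,
            "output": self.output,
        }


def _check_keys(block: dict, allowed: set, path: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key {path}.{key}")


def resolve_config(raw: dict) -> RunConfig:
    """Validate a raw mapping and resolve all defaults.

    Provenance marks each model/evolution parameter as "user" or
    "default-calibrated".
    """
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<root>")

    scenario = dict(raw.get("scenario") or {})
    _check_keys(scenario, _SCENARIO_KEYS, "scenario")
    preset = scenario.pop("preset", None)
    evo_kwargs: dict[str, Any] = {}
    if preset is not None:
        if preset not in _PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        spec = _PRESETS[preset]
        scenario.setdefault("kind", spec["scenario"])
        if spec["k_ell_null"]:
            evo_kwargs["k_ell"] = 0.0
        if spec["scenario"] == "ten_resource":
            evo_kwargs["k_ell"] = {0: 0.1, 1: 0.05}
    if "kind" not in scenario:
        raise ConfigError("scenario.kind (or scenario.preset) is required")
    if scenario["kind"] not in ("two_resource", "ten_resource", "custom"):
        raise ConfigError(f"unknown scenario.kind {scenario['kind']!r}")

    model = dict(raw.get("model") or {})
    _check_keys(model, _MODEL_KEYS, "model")
    provenance = {}
    for key in sorted(_MODEL_KEYS):
        provenance[f"model.{key}"] = "user" if key in model else "default-calibrated"
    _validate_model_overrides(model)

    evo_raw = dict(raw.get("evolution") or {})
    tol_raw = dict(raw.get("tolerances") or {})
    _check_keys(evo_raw, _EVOLUTION_KEYS, "evolution")
    _check_keys(tol_raw, _TOLERANCE_KEYS, "tolerances")
    for key in sorted(_EVOLUTION_KEYS):
        provenance[f"evolution.{key}"] = ("user" if key in evo_raw or key in tol_raw
                                          else "default-calibrated")
    evo_kwargs.update(tol_raw)
    evo_kwargs.update(evo_raw)
    if isinstance(evo_kwargs.get("k_ell"), dict):
        evo_kwargs["k_ell"] = {int(k): float(v)
                               for k, v in evo_kwargs["k_ell"].items()}
    if isinstance(evo_kwargs.get("k_eta"), dict):
        evo_kwargs["k_eta"] = {int(k): float(v)
                               for k, v in evo_kwargs["k_eta"].items()}
    try:
        evolution = EvoRunConfig(**evo_kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    _validate_evolution(evolution)

    return RunConfig(scenario=scenario, model=model, evolution=evolution,
                     output=raw.get("output"), provenance=provenance)


def _validate_model_overrides(model: dict) -> None:
    # delegate full validation to Model1Params, but give config-level
    # messages for the common bounded parameters
    if "gamma" in model and not (0 < model["gamma"] < 1):
        raise ConfigError("model.gamma must satisfy 0 < gamma < 1 "
                          "(juvenile feeding is scaled below the adult rate)")
    if "epsilon" in model and not (0 < model["epsilon"] <= 1):
        raise ConfigError("model.epsilon must satisfy 0 < epsilon <= 1")
    for key in ("rho", "alpha", "nu", "w", "delta_max", "delta_A", "tau",
                "F_max_each", "D"):
        if key in model and not model[key] > 0:
            raise ConfigError(f"model.{key} must be strictly positive")


def _validate_evolution(evo: EvoRunConfig) -> None:
    for name in ("dt_evo", "cessation_threshold", "branch_offset",
                 "extinction_threshold"):
        if getattr(evo, name) <= 0:
            raise ConfigError(f"evolution.{name} must be positive")
    if not evo.branch_offset < 0.1:
        raise ConfigError("evolution.branch_offset must be small (<< 1)")
    for spec in (evo.k_eta, evo.k_ell):
        vals = spec.values() if isinstance(spec, dict) else [spec]
        if any(v < 0 for v in vals):
            raise ConfigError("trait-update rate constants must be >= 0")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    return resolve_config(raw)


def save_config(config: RunConfig, path) -> None:
    """Serialize a fully resolved config; load(save(c)) round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_mapping(), fh, sort_keys=True)


def preset_config(name: str, **overrides) -> RunConfig:
    """Resolved configuration for a named preset run."""
    if name == "fig4a":
        raise ConfigError("the fig4a preset is a sweep; use the threshold-map "
                          "command or evolution.preset_fig4a")
    raw = {"scenario": {"preset": name}}
    raw.update(overrides)
    return resolve_config(raw)
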