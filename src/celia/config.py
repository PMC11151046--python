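"""YAML run configuration: validation, defaults materialisation, stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import KineticParams, ValidationError
from .circuits import (
    build_converter,
    build_exponential_module,
    build_inverter_module,
    build_linear_module,
    compose,
)

__all__ = ["RunConfig", "load_config", "build_circuit_from_config"]

_CIRCUIT_DEFAULTS = {
    "modules": ["exponential", "linear"],
    "aT_alpha": 20.0,
    "pT_alpha": 0.0,
    "rT_alpha": 50.0,
    "alpha_to_omega": 2.0,
    "rT_omega": 200.0,
    "beta_to_omega": 10.0,
    "alpha_k_beta": 1.0,
    "miR_to_alpha": 10.0,
    "alpha0": 0.0,
    "beta0": 2.0,
    "target_molar": 0.0,
    "target_name": "miR",
    "activated_fraction": 0.0,
}
_SIMULATE_DEFAULTS = {"t_end_min": 1000.0, "dt_out_min": 2.0}
_NOISE_DEFAULTS = {"well_scale_cv": 0.05, "additive_sd": 0.01, "baseline_offset_sd": 0.02}
_ANALYSIS_DEFAULTS = {
    "at_channel": "alpha",
    "endpoint_channel": "omega",
    "at_threshold_fraction": 0.2,
    "baseline_correct": True,
}
_CALIBRATION_DEFAULTS = {"replicates": 3, "include_blank": True}
_KNOWN_MODULES = ("converter", "exponential", "linear", "inverter")


@dataclass
class RunConfig:
    circuit: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)

    def __post_init__(self):
        self.circuit = _merge("circuit", _CIRCUIT_DEFAULTS, self.circuit)
        kp_defaults = KineticParams().to_dict()
        self.params = _merge("params", kp_defaults, self.params)
        self.simulate = _merge("simulate", _SIMULATE_DEFAULTS, self.simulate)
        self.noise = _merge("noise", _NOISE_DEFAULTS, self.noise)
        self.analysis = _merge("analysis", _ANALYSIS_DEFAULTS, self.analysis)
        self.calibration = _merge("calibration", _CALIBRATION_DEFAULTS, self.calibration)
        for mod in self.circuit["modules"]:
            if mod not in _KNOWN_MODULES:
                raise ValidationError("circuit.modules", f"unknown module {mod!r}")

    def kinetic_params(self) -> KineticParams:
        return KineticParams(**self.params)

    def materialized(self) -> dict:
        return {
            "circuit": self.circuit,
            "params": self.params,
            "simulate": self.simulate,
            "noise": self.noise,
            "analysis": self.analysis,
            "calibration": self.calibration,
        }

    @property
    def hash(self) -> str:
        blob = json.dumps(self.materialized(), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _merge(block: str, defaults: dict, overrides: dict) -> dict:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValidationError(block, f"unknown keys {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides or {})
    return out


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config", "top level must be a mapping")
    known = {"circuit", "params", "simulate", "noise", "analysis", "calibration"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError("config", f"unknown top-level keys {sorted(unknown)}")
    return RunConfig(**{k: raw.get(k, {}) for k in known})


def build_circuit_from_config(cfg: RunConfig):
    """Assemble the network described by the circuit block."""
    c = cfg.circuit
    p = cfg.kinetic_params()
    mods = []
    for name in c["modules"]:
        if name == "converter":
            mods.append(
                build_converter(c["miR_to_alpha"], c["target_molar"], p, target_name=c["target_name"])
            )
        elif name == "exponential":
            mods.append(
                build_exponential_module(c["aT_alpha"], c["pT_alpha"], c["rT_alpha"], c["alpha0"], p)
            )
        elif name == "linear":
            mods.append(
                build_linear_module(
                    c["alpha_to_omega"], c["rT_omega"], p, activated_fraction=c["activated_fraction"]
                )
            )
        elif name == "inverter":
            mods.append(
                build_inverter_module(c["beta_to_omega"], c["beta0"], c["alpha_k_beta"], c["rT_omega"], p)
            )
    return compose(mods)
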