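"""Structured configuration: defaults, YAML/JSON loading, validation.

One nested mapping covers every tunable of the simulator; `load_config`
fills omitted keys with the documented defaults and rejects unknown keys.
Any entry is addressable by a dotted key (``"network.n_excitatory"``).
The default values here are the package's frozen "stated world": the
scaled-down network, gains and schedule under which the staged protocol
reproduces its qualitative results.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .params import (ConfigurationError, InhibPlasticityParams, NeuronParams,
                     NetworkSpec, ScalingParams)

SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "network": {
        "n_excitatory": 2000,
        "n_inhibitory": 500,
        "connection_probability": 0.02,
        "baseline_weights": {"ee": 0.08, "ei": 0.08, "ie": 0.6, "ii": 0.6},
    },
    "neuron": {
        "tau_m": 20.0, "v_rest": -60.0, "v_thresh": -50.0, "v_reset": -60.0,
        "tau_ref": 5.0, "e_exc": 0.0, "e_inh": -80.0,
        "tau_exc": 5.0, "tau_inh": 10.0,
        "drive_rate_hz": 310.0, "drive_weight": 0.08, "drive_current_mv": 0.0,
    },
    "plasticity": {
        "eta": 0.01, "target_rate_hz": 5.0, "tau_stdp": 20.0,
        "weight_max": 50.0, "enabled": True,
    },
    "scaling": {
        "interval_ms": 1000.0, "target_rate_hz": 5.0, "gain": 0.02,
        "rate_floor_hz": 0.1, "factor_min": 0.5, "factor_max": 2.0,
        "enabled": False,
    },
    "assemblies": {
        "n_per_assembly": 100,
        "labels": ["red", "green", "yellow", "blue"],
        "within_assembly_gain": 10.0,
    },
    "associations": {
        "pairs": [["red", "green"], ["blue", "yellow"]],
        "between_assembly_gain": 5.0,
    },
    "stimulus": {
        "disinhibition_factor": 0.1,
        "duration_ms": 1000.0,
    },
    "schedule": {
        "compression": 10.0,
        "base_eta": 0.01,
        "downscale_fraction": 0.15,
        "probe_interval_s": 40.0,
        "trials_per_probe": 5,
        "probe_duration_ms": 1000.0,
        "train_stimulation": True,
        "train_duration_ms": 1000.0,
        "scan_rebalance_ms": 40000.0,
        "timeline_window_ms": 2000.0,
        "step_ms": 0.1,
    },
    "readout": {
        "grid_map_window_ms": 1000.0,
        "timeline_window_ms": 2000.0,
        "coactivation_threshold": 3.0,
        "background_sd_floor_hz": 0.5,
        "latching_threshold_factor": 3.0,
        "latching_min_distinct": 3,
        "latching_span_s": 10.0,
    },
}

_RANGES = {
    "schedule.downscale_fraction": (0.0, 1.0, "in [0, 1)"),
    "stimulus.disinhibition_factor": (0.0, 1.0, "in [0, 1)"),
    "network.connection_probability": (0.0, 1.0 + 1e-12, "in [0, 1]"),
}


def _merge(defaults: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        dotted = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key {dotted!r}")
        if isinstance(defaults[key], dict) and key != "baseline_weights":
            if not isinstance(val, dict):
                raise ConfigurationError(
                    f"{dotted!r} must be a mapping")
            out[key] = _merge(defaults[key], val, prefix=dotted + ".")
        else:
            out[key] = copy.deepcopy(val)
    return out


def _check_ranges(cfg: dict) -> None:
    for dotted, (lo, hi, desc) in _RANGES.items():
        val = get_key(cfg, dotted)
        if not (lo <= val < hi):
            raise ConfigurationError(f"{dotted} = {val} must lie {desc}")


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Validated configuration with defaults filled in.

    ``path`` may be YAML or JSON (or None for pure defaults); ``overrides``
    is merged on top. Unknown keys are rejected with the offending dotted
    key named; range-constrained entries are checked here so errors appear
    at load time rather than mid-run.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("configuration root must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema_version {cfg['schema_version']!r}")
    _check_ranges(cfg)
    # instantiate the typed params once so their validators run too
    objects_from_config(cfg)
    return cfg


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def get_key(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise ConfigurationError(f"unknown configuration key {dotted!r}")
    return node


def set_key(cfg: dict, dotted: str, value) -> dict:
    parts = dotted.split(".")
    get_key(cfg, dotted)  # existence check
    node = cfg
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value
    return cfg


def latching_control_overrides() -> dict:
    """Configuration overrides for the homeostatic-scaling control run.

    The control replaces inhibitory plasticity with multiplicative scaling
    of excitatory synapses as the stabilizer. Scaling only has destabilizing
    leverage when recurrent excitation carries the network, so the control
    operates the same architecture at a recurrence-dominated point: stronger
    E→E/E→I baselines and weaker background drive, where the naive network
    is unstable until scaling reins it in. With assemblies embedded there,
    the network shows spontaneous serial assembly activation (latching);
    the inhibitory-plasticity default run does not.
    """
    return {
        "network": {"baseline_weights": {"ee": 0.12, "ei": 0.12,
                                         "ie": 0.6, "ii": 0.6}},
        "neuron": {"drive_rate_hz": 220.0},
        "scaling": {"gain": 0.1, "enabled": True},
    }


def objects_from_config(cfg: dict):
    """Typed parameter bundle (NetworkSpec, NeuronParams, plasticity,
    scaling) from a validated configuration mapping."""
    net = cfg["network"]
    spec = NetworkSpec(
        n_excitatory=net["n_excitatory"], n_inhibitory=net["n_inhibitory"],
        connection_probability=net["connection_probability"],
        baseline_weights=dict(net["baseline_weights"]),
        seed=cfg["seed"]).validate()
    params = NeuronParams(**cfg["neuron"]).validate()
    plast = InhibPlasticityParams(**cfg["plasticity"]).validate()
    scaling = ScalingParams(**cfg["scaling"]).validate()
    return spec, params, plast, scaling
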