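"""Pipeline configuration: documented defaults, strict merging, provenance."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

#: Every tunable of the pipeline, with defaults equal to the documented
#: design decisions.  Unknown keys in a user config are rejected.
DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "sampling_rate_hz": 40000.0,
        "noise_sd_v": 5.0e-5,
        "lobe_width_ms": 0.8,
        "artifact_amplitude_v": 0.02,
        "tail_s": 0.4,
    },
    "geometry": {
        "electrode_spacing_m": 0.01,
        "anode_separation_m": 0.02,
        "stim_to_first_anode_m": 0.084,
    },
    "filter": {
        "low_hz": 120.0,
        "high_hz": 1200.0,
        "order": 4,
    },
    "detect": {
        "threshold_k": 4.0,
        "blanking_ms": {"EStim": 2.0, "MStim": 0.0, "UStim": 0.0},
        "lobe_window_ms": [0.3, 3.0],
        "dead_time_ms": 1.0,
        "onset_dead_time_ms": 5.0,
    },
    "match": {
        "velocity_window_mps": [3.0, 30.0],
    },
    "classify": {
        "velocity_boundary_mps": 12.0,
        "amplitude_boundary_v": None,
    },
    "latency": {
        "response_window_s": 0.2,
    },
    "trial": {
        "n_mstim": 60,
        "n_ustim": 60,
        "start_s": 0.5,
        "interval_s": 0.4,
        "region": "posterior",
        "leus": {
            "carrier_frequency_hz": 1.1e6,
            "n_cycles": 175,
            "prf_hz": 125.0,
            "n_pulses": 20,
            "pressure_amplitude_pa": 6.6e6,
        },
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and not isinstance(value, dict):
            raise ConfigError(f"config key {here} must be a mapping")
        if isinstance(base[key], dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def make_config(overrides: dict | None = None) -> dict:
    """Full configuration with ``overrides`` merged onto the defaults."""
    return _merge(DEFAULTS, overrides or {})


def read_config(path: str | Path | None) -> dict:
    """Load a YAML config file and merge it onto the defaults."""
    if path is None:
        return make_config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return make_config(raw)


def config_hash(config: dict) -> str:
    """Stable provenance hash of a configuration."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()
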