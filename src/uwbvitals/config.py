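"""Merged run configuration with the pipeline's standard defaults.

All tunables of the pipeline live in one nested mapping; a YAML/JSON file
overrides defaults key by key and unknown keys are rejected.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

DEFAULTS: dict[str, dict[str, Any]] = {
    "frames": {
        "fs_slow_hz": 110.0,
        "n_bins": 256,
        "bin_spacing_m": 1.0 / 256,
    },
    "regions": {
        "phone": [0, 64],
        "vitals": [64, 192],
    },
    "clutter": {
        "alpha_vitals": 0.97,
        "alpha_phone": 0.8,
        "k_margin": 10,
    },
    "fit": {
        "omega_min_hz": 0.05,
        "omega_max_hz": 3.0,
        "grid_points": 1024,
        "refine_iters": 3,
        "include_offset": False,
    },
    "select": {
        "resp_band_hz": [0.15, 0.5],
        "amp_threshold": "auto",
        "auto_factor": 3.0,
        "smooth_window": 5,
        "r_sq_threshold": 0.3,
        "max_candidates": 9,
    },
    "recon": {
        "width_level": 0.5,
        "max_lag": None,
        "hysteresis_frac": 0.2,
        "min_segment": 33,
        "score_context": 220,
    },
    "spect": {
        "nfft": 2**15,
        "resp_band_hz": [0.15, 0.5],
        "heart_band_hz": [0.8, 2.0],
    },
    "phone": {
        "threshold1": 3.0,
        "threshold2": 0.8,
        "t_hold_s": 1.2,
        "t_y_s": 1.0,
        "alpha": 0.8,
        "k_margin": 10,
    },
    "vitals_window": {
        "window_s": 30.0,
        "hop_s": 5.0,
    },
}


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML/JSON override file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path} must contain a mapping at top level")
    return _merge(DEFAULTS, data)
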