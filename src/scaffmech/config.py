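"""Configuration handling for the command-line interface.

A YAML file may override any default; unknown keys are rejected so typos
surface early.  All defaults are the published material constants and study
settings, so an empty configuration reproduces the reference scenario.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "material": {
        "E_HA": 114.0,        # GPa, hydroxyapatite Young's modulus
        "nu_HA": 0.27,        # hydroxyapatite Poisson's ratio
    },
    "design": {
        "epsilon": 10.0,      # crack density parameter, dimensionless
        "r_gran": 500.0,      # granule radius, um
        "phi_macro_0": 0.4,   # initial macroporosity
        "k_res": 0.0,         # resorption rate, 1/week
        "k_growth": 7.0,      # bone ingrowth rate, um/week
        "phi_micro_0": 0.445, # initial microporosity
        "phi_meso": 0.189,    # mesoporosity
    },
    "time_grid": {
        "t_start": 0.0,       # weeks
        "t_end": 30.0,        # weeks
        "dt": 0.5,            # weeks
    },
    "target_band": [5.0, 19.0],  # GPa
    "solver": {
        "tol_level1": 1e-10,
        "tol_level3": 1e-9,
        "max_iter_level1": 500,
        "max_iter_level3": 200,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"configuration section {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)
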