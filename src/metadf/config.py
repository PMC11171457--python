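"""Centralized run configuration for the command-line pipelines.

All stage defaults live in :data:`DEFAULTS`; a YAML config file may
override any subset, unknown keys are rejected.  One global seed is split
deterministically into per-stage streams.
"""

from __future__ import annotations

import hashlib

import numpy as np
import yaml

from .exceptions import ConfigError

DEFAULTS = {
    "seed": 0,
    "output_dir": ".",
    "verbosity": 1,
    "landscape": {
        "ndim": 2,
        "temperature": 300.0,
        "params": {
            "r_c": 2.0, "z_wall": 10.0,
            "z_M1": 2.8, "z_M2": 5.2, "z_B": 4.2,
            "d_M1": -27.0, "d_M2": -8.0, "b": 5.0,
            "w_M1": 0.35, "w_B": 0.60, "w_M2": 0.35,
            "c_gamma": 3.0, "gamma_period": 1,
            "coupling_center": 2.8, "coupling_width": 1.0,
            "switch_on": 7.0, "switch_off": 8.0,
        },
    },
    "sampler": {
        "n_steps": 100_000, "timestep": 0.002, "friction": 2.0,
        "mass_z": 50.0, "mass_gamma": 10.0, "temperature": 300.0,
        "n_walkers": 4, "equilibration_fraction": 0.1,
        "wall_stiffness": 500.0, "lower_wall_stiffness": 500.0,
        "record_stride": 1,
    },
    "bias": {
        "enabled": True, "w0": 1.0, "sigma_z": 0.2, "sigma_gamma": 0.25,
        "stride": 100, "biasfactor": None,  # None = standard metadynamics
    },
    "metadf": {
        "bin_width": 0.1, "weighting": "bias",
        "equilibration_fraction": 0.1, "max_gap_bins": 5,
    },
    "adsorption": {
        "bulk_onset": 6.7, "delta_m1": 1.5, "temperature": 300.0,
        "min_prominence": 0.5,
    },
    "benchmark": {
        "tolerance": 1.0, "sustain": 10, "n_seeds": 5,
        "budget_steps": 2_000_000, "burn_in_steps": 1000,
    },
    "isotherm": {
        "n_bootstrap": 2000, "temperature": 298.15,
        "sim": {"K": 2.7e5, "rct0": 200.0, "rct_inf": 1200.0,
                "noise": 0.02, "replicates": 2},
    },
    "hydration": {
        "bin_width": 0.1, "d_max": 10.0, "prominence": 1.0,
        "hbond_cutoff": 2.5, "surface_element": "Ti", "species": "O",
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and a dict."""
    cfg = DEFAULTS
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of the effective configuration."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)


def stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds derived from the global seed."""
    ss = np.random.SeedSequence(int(global_seed))
    names = ["sampler", "benchmark", "isotherm", "hydration"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}
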