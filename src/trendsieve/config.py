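"""YAML configuration for the CLI and batch runs.

A config file may set any subset of the keys below; unset keys keep the
reference defaults.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "horizon_hours": 48.0,
    "window_hours": 2.0,
    "detectors": {
        "max_iter": 150,
        "tol": 1e-8,
        "n_starts": 5,
        "polish_top": 1,
        "seed": 0,
    },
    "mining": {
        "alphabet": 4,
        "discretizer": "sax",
        "min_support": 0.6,
        "k_max": 3,
        "epsilon": 0.0,
    },
    "cv": {
        "folds": 20,
        "dev_fraction": 0.30,
        "seed": 0,
        "n_estimators": 200,
    },
    "synthetic": {
        "n_patients": 2000,
        "prevalence": 0.57,
        "samples_per_hour": 1.0,
        "missing_window_prob": 0.1,
        "effect_size": 1.0,
        "seed": 0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the defaults; None gives the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    return _merge(DEFAULTS, user)


__all__ = ["DEFAULTS", "load_config"]
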