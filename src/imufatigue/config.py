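"""Config-file handling: built-in defaults < YAML file < CLI flags."""
from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "sampling": {"rate": 50.0},
    "segmentation": {
        "reference_channel": "gx",
        "min_period": 1.0,
        "prominence_fraction": 0.3,
        "smoothing_window": 5,
    },
    "preprocessing": {"dumbbell_mass": 4.5, "rpe_tolerance": 2.0},
    "features": {"raw_rms": False, "reference_channel": "gx"},
    "similarity": {
        "alpha": 0.4,
        "beta": 0.6,
        "gamma": 14.0,
        "normalize_signal": True,
        "sample_reps": 15,
        "signal_channel": "gx",
    },
    "model": {
        "base_learner": "decision_tree",
        "n_rounds": 50,
        "learning_rate": 1.0,
        "tree_max_depth": 3,
        "ann_hidden_units": 16,
        "ann_epochs": 200,
        "seed": 0,
    },
    "budget": {"basis": 75, "fractions": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6]},
    "sweeps": {"gamma_grid_max": 30, "gamma_grid_step": 1, "alpha_step": 0.05},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict[str, Any]:
    """Layer the optional YAML file and explicit overrides over the defaults."""
    config = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    return config
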