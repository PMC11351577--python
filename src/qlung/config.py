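"""Structured run configuration with full defaulting and strict keys.

A run config is a nested mapping (YAML on disk). Every documented key has a
default; unknown keys are rejected by name so typos fail loudly instead of
silently falling back.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["DEFAULTS", "load_config", "merge_config", "config_digest"]

DEFAULTS: dict = {
    "seed": 0,
    "data": {
        "n_subjects": 300,
        "image_size": 64,
        "class_proportions": [0.25, 0.25, 0.5],  # normal, benign, malignant
        "noise_sd": 4.0,
    },
    "backbone": {
        "seed": 0,
        "input_size": 64,
    },
    "svd": {
        "n_components": 5,
    },
    "quantum": {
        "n_qubits": 5,
        "n_var_layers": 2,
    },
    "head": {
        "sizes": [100, 50, 20, 3],
    },
    "train": {
        "epochs": 30,
        "batch_size": 16,
        "learning_rate": 1e-3,
        "train_frac": 0.70,
        "val_frac": 0.15,
        "test_frac": 0.15,
        "patience": None,
    },
    "eval": {
        "positive_class": "malignant",
    },
}


def merge_config(overrides: dict | None) -> dict:
    """Defaults overlaid with ``overrides``; unknown keys raise by name."""
    merged = copy.deepcopy(DEFAULTS)
    if not overrides:
        return merged

    def merge(base: dict, over: dict, path: str) -> None:
        for key, value in over.items():
            where = f"{path}.{key}" if path else key
            if key not in base:
                raise ValidationError(f"unknown config key: {where}")
            if isinstance(base[key], dict):
                if not isinstance(value, dict):
                    raise ValidationError(f"config section {where} must be a mapping")
                merge(base[key], value, where)
            else:
                base[key] = value

    merge(merged, overrides, "")
    return merged


def load_config(path=None) -> dict:
    """Load a YAML config file (or None for pure defaults) and validate."""
    overrides = None
    if path is not None:
        text = Path(path).read_text()
        overrides = yaml.safe_load(text) or {}
        if not isinstance(overrides, dict):
            raise ValidationError("config file must contain a mapping")
    return merge_config(overrides)


def config_digest(config: dict) -> str:
    """Short stable digest of a config for run logs."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
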