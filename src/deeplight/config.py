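"""Plain-text (YAML) run configuration with validation and defaults.

All method defaults surface here exactly as used throughout the package:
learning rate 1e-4, batch size 32, gradient-clip threshold 5, LRP stabilizer
0.001, smoothing FWHM 3 mm, highpass cutoff 128 s, map threshold percentile
90, relevance window 5-15 s after block onset.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "simulate": {
        "grid_shape": [16, 16, 12],
        "tr": 1.0,
        "n_states": 4,
        "block_length": 20.0,
        "blocks_per_state": 2,
        "rest_length": 10.0,
        "effect_amplitude": 5.0,
        "noise_sd": 1.0,
        "drift_slope": 0.01,
        "drift_sine_period": 120.0,
        "n_subjects": 8,
        "seed": 0,
    },
    "preprocess": {
        "fwhm": 3.0,
        "highpass": 128.0,
        "mask_fraction": 0.05,
    },
    "train": {
        "learning_rate": 1e-4,
        "batch_size": 32,
        "max_epochs": 60,
        "clip_norm": 5.0,
        "hidden_size": 40,
        "patience": 5,
        "validation_fraction": 0.2,
        "seed": 0,
    },
    "relevance": {
        "epsilon": 0.001,
        "window": [5.0, 15.0],
    },
    "maps": {
        "fwhm": 3.0,
        "percentile": 90.0,
        "positive_only": True,
    },
    "baselines": {
        "fdr_q": 0.1,
        "searchlight_radius_mm": 5.6,
        "folds": 5,
        "lambda_grid": [0.1, 1.0, 10.0],
    },
    "pipeline": {
        "stages": ["simulate", "preprocess", "train", "decode", "relevance", "maps", "evaluate"],
        "out_dir": "runs",
    },
}

_RANGES = {
    ("maps", "percentile"): (0.0, 100.0, False),
    ("train", "learning_rate"): (0.0, None, False),
    ("train", "batch_size"): (1, None, True),
    ("train", "clip_norm"): (0.0, None, False),
    ("preprocess", "fwhm"): (0.0, None, True),
    ("preprocess", "highpass"): (0.0, None, False),
    ("relevance", "epsilon"): (0.0, None, False),
    ("simulate", "noise_sd"): (0.0, None, True),
    ("simulate", "tr"): (0.0, None, False),
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _check_value(section: str, key: str, value, default, errors: list[str]):
    if isinstance(default, bool):
        expected = bool
    elif isinstance(default, (int, float)) and not isinstance(default, bool):
        expected = (int, float)
    elif isinstance(default, list):
        expected = list
    elif isinstance(default, str):
        expected = str
    else:
        expected = object
    if not isinstance(value, expected):
        errors.append(
            f"{section}.{key}: expected {getattr(expected, '__name__', 'number')}, "
            f"got {type(value).__name__} ({value!r})"
        )
        return
    rng = _RANGES.get((section, key))
    if rng is not None:
        lo, hi, lo_inclusive = rng
        if (value < lo) or (value == lo and not lo_inclusive):
            errors.append(f"{section}.{key}: must be {'>=' if lo_inclusive else '>'} {lo}")
        if hi is not None and value >= hi:
            errors.append(f"{section}.{key}: must be < {hi}")


def validate_config(config: dict | str | Path | None) -> dict:
    """Fill defaults, reject unknown keys, and report all violations at once."""
    if config is None:
        raw = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = copy.deepcopy(config)
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    merged = copy.deepcopy(DEFAULTS)
    errors: list[str] = []
    for section, values in raw.items():
        if section not in merged:
            errors.append(f"unknown section {section!r}")
            continue
        if not isinstance(values, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, value in values.items():
            if key not in merged[section]:
                errors.append(f"unknown key {section}.{key}")
                continue
            _check_value(section, key, value, merged[section][key], errors)
            if not errors or errors[-1].split(":")[0] != f"{section}.{key}":
                merged[section][key] = value
    if errors:
        raise ConfigError(errors)
    return merged
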