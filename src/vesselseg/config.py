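"""Pipeline configuration: nested defaults, YAML loading, strict validation.

Unknown keys are rejected rather than ignored — a misspelled parameter
should fail loudly, not silently fall back to a default.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "gabor": {
        "f0": 0.25,
        "ratio": 0.5,
        "n_freqs": 5,
        "n_orients": 8,
        "gamma": 2.0,
        "eta": 2.0,
        "phi": 0.0,
        "sigma_coeff": 0.56,
        "truncate": 3.0,
        "smooth_factor": 0.5,
    },
    "kmeans": {
        "k": 2,
        "max_iter": 300,
        "init": "stain-supervised",
        "seed": 0,
        "standardize": True,
        "log_compress": True,
    },
    "mask": {
        "od_threshold": 0.10,
        "strong_od_threshold": 0.22,
        "background_window_px": 31,
        "fill_holes": True,
    },
    "structures": {
        "min_area_px": 10,
    },
    "forest": {
        "n_trees": 64,
        "subset_size": 3,
        "gain_epsilon": 1.0e-6,
        "min_samples": 2,
        "max_depth": 16,
        "candidate_grid": 32,
        "seed": 0,
    },
    "synthesis": {
        "image_size": [256, 256],
        "n_vessels": 6,
        "n_distractors": 4,
        "vessel_width_px": [3.0, 10.0],
        "vessel_length_px": [30.0, 200.0],
        "artery_width_px": [20.0, 40.0],
        "artery_length_px": [60.0, 180.0],
        "neuron_diameter_px": [8.0, 20.0],
        "stain_intensity": [0.42, 0.07],
        "entropy_tol": 0.15,
        "max_refine_iter": 50,
    },
    "evaluation": {
        "iou_threshold": 0.3,
        "bin_width": 0.5,
        "entropy_low": 3.0,
        "entropy_high": 8.0,
    },
    "benchmark": {
        "n_scenes": 200,
        "entropy_range": [3.2, 7.8],
        "train_fraction": 0.7,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file (if given), then explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable digest identifying a configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)
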