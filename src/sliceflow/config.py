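"""Run configuration: schema-validated nested config with field defaults
mirroring the reference setup (8 coupling layers, 512-dim embedding,
sigma 0.06, tau 1.0, Adam lr 0.001, backbone taps at layers 2 and 3).

Unknown keys are rejected so typos fail loudly. A stable hash of the
model-defining sections guards checkpoint/config consistency.
"""

from __future__ import annotations

import hashlib
import json

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "phantom": {
        "shape": [32, 64, 64],
        "n_normal": 20,
        "n_anomalous": 10,
        "lesion_radius_range": [3.0, 6.0],
        "lesion_contrast": 0.35,
        "n_lesions_range": [1, 3],
        "deformation_scale": 1.5,
        "noise_sd": 0.02,
    },
    "preprocess": {"crop": None, "rescale": True, "resize_pad": None},
    "backbone": {"name": "wide_resnet50_2", "layers": [2, 3]},
    "encoder": {"patch_size": 3, "target_dim": 512},
    "edc": {"epochs": 1, "lr": 0.001},
    "flow": {"n_coupling": 8, "hidden": 512, "cond_dim": 128, "clamp": 1.9},
    "loss": {"variant": "triplet", "sigma": 0.06, "tau": 1.0, "beta": 10.0},
    "aggregation": {"window": 3},
    "train": {"epochs": 5, "lr": 0.001},
}


class ConfigError(ValueError):
    pass


def _merge(defaults, override, path=""):
    if override is None:
        return defaults
    if not isinstance(override, dict):
        raise ConfigError(f"config section '{path or '<root>'}' must be a mapping")
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key '{path + key}'")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run config, merge onto defaults, reject unknown keys."""
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = _merge(DEFAULTS, cfg)
    if overrides:
        merged = _merge(merged, overrides)
    variant = merged["loss"]["variant"]
    if variant not in ("triplet", "bgspp", "prl", "none"):
        raise ConfigError(f"loss.variant '{variant}' not in (triplet, bgspp, prl, none)")
    return merged


def model_hash(cfg: dict) -> str:
    """Hash of the model-defining sections (backbone/encoder/flow/aggregation)."""
    relevant = {k: cfg[k] for k in ("backbone", "encoder", "flow", "aggregation")}
    blob = json.dumps(relevant, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
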