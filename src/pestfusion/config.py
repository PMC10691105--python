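"""Run configuration: defaults, YAML loading, overrides, stable hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "merge_overrides", "config_hash"]

CONFIG_SCHEMA_VERSION = 1

_DEFAULTS: dict = {
    "backbone": {"name": "tiny", "image_size": 64, "dropout_rate": 0.5,
                 "channels": 32},
    "eflm": {"enabled": True, "num_blocks": 3, "gradual": True,
             "test_lambda": 0.5},
    "affm": {"enabled": True, "heads": 4, "qk_mask": True, "v_mask": True,
             "p": None},          # None -> 1 / (2 N_t)
    "head": {"voting": "soft"},   # soft | hard | none
    "optim": {"lr": 1.0e-3, "momentum": 0.9, "weight_decay": 1.0e-4,
              "epochs": 20, "lr_decay_factor": 0.1, "lr_decay_at_epoch": 10},
    "data": {"manifest": None, "n_t": 5, "batch_anchors": 16, "seed": 0},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _deep_update(base: dict, extra: dict, path: str = "") -> None:
    for key, val in extra.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            _deep_update(base[key], val, here)
        else:
            base[key] = val


def load_config(path=None) -> dict:
    """Defaults, optionally updated from a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        _deep_update(cfg, loaded)
    return cfg


def merge_overrides(cfg: dict, overrides: dict[str, object]) -> dict:
    """Apply dotted-key overrides like {'affm.enabled': False}."""
    cfg = copy.deepcopy(cfg)
    for dotted, value in overrides.items():
        node = cfg
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part not in node:
                raise KeyError(f"unknown config key: {dotted}")
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key: {dotted}")
        node[parts[-1]] = value
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable under key reordering: canonical sorted-key JSON, sha256."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
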