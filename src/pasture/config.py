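"""Layered configuration: packaged defaults < config file < CLI flags."""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import yaml

from .growth import GrowthParameters


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        elif v is not None:
            out[k] = v
    return out


def packaged_defaults() -> dict:
    ref = resources.files("pasture.params") / "defaults.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_config(config_path=None, overrides: dict | None = None) -> dict:
    """Merge packaged defaults, an optional YAML file, and explicit overrides."""
    cfg = packaged_defaults()
    if config_path is not None:
        with open(config_path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def growth_params_from_config(cfg: dict) -> GrowthParameters:
    g = cfg["growth"]
    return GrowthParameters(
        rue=g["rue"],
        k_ext=g["k_ext"],
        par_fraction=g["par_fraction"],
        sla=g["sla"],
        leaf_partition=g["leaf_partition"],
        t_base=g["t_base"],
        t_opt=tuple(g["t_opt"]),
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for run manifests."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
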