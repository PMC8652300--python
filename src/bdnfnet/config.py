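"""Pipeline configuration: YAML loading, validation and defaults.

Every stage threshold carries its standard default (QC call rates, HWE
floor, MAF cut, clump r2/window, network r-min/fold/flank, PCA pruning,
pICA z-threshold ...).  A config is a plain nested dict; ``load_config``
validates types and unknown keys against the schema below and fills
defaults, and every pipeline run writes back the frozen resolved config.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "ConfigError", "load_config", "resolve_config",
           "dump_config"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "results/pipeline",
    "stages": ["simulate", "build-network", "score", "adversity", "irt",
               "growth", "pica"],
    "simulate": {
        "n_children": 157,
        "visit_ages": [6, 12, 18, 36],
        "n_imaging": 47,
    },
    "network": {
        "rmin": 0.5,
        "fold": 1.5,
        "flank": 500,
    },
    "score": {
        "snp_call_rate": 0.95,
        "sample_call_rate": 0.90,
        "maf_min": 0.05,
        "hwe_floor": 1e-40,
        "clump_r2": 0.2,
        "clump_window": 500_000,
        "pca_maf_min": 0.05,
        "pca_prune_r2": 0.20,
        "pca_window_kb": 50,
        "pca_step": 5,
        "pca_k": 3,
    },
    "adversity": {
        "percentile_mode": False,
    },
    "irt": {
        "tol": 1e-4,
        "max_iter": 200,
        "extreme_adjust": 0.3,
    },
    "growth": {
        "random": "age+age2",
        "compute_f2": False,
        "source": "cohort_table",
    },
    "pica": {
        "lam": 1.0,
        "max_iter": 512,
        "tol": 1e-6,
        "z_thresh": 2.5,
        "mask_threshold": 0.0,
        "welch": False,
    },
}

_SCALARS = (int, float, str, bool)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        base = defaults[key]
        if isinstance(base, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(base, val, here)
        elif isinstance(base, list):
            if not isinstance(val, list):
                raise ConfigError(f"{here}: expected a list")
            out[key] = list(val)
        else:
            if isinstance(base, bool) and not isinstance(val, bool):
                raise ConfigError(f"{here}: expected a boolean")
            if isinstance(base, (int, float)) and not isinstance(val, (int, float)):
                raise ConfigError(f"{here}: expected a number")
            if isinstance(base, str) and not isinstance(val, str):
                raise ConfigError(f"{here}: expected a string")
            out[key] = val
    return out


def resolve_config(user: dict | None = None) -> dict:
    """Merge user overrides over the defaults, rejecting unknown keys."""
    cfg = _merge(DEFAULTS, user or {})
    known = set(DEFAULTS["stages"])
    bad = [s for s in cfg["stages"] if s not in known]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    return cfg


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return resolve_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_config(user)


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
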