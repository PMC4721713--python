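"""Configuration defaults and YAML overrides.

Configuration is a plain nested dict; ``load_config`` deep-merges a user
YAML file over ``DEFAULTS`` and ``get`` reads dotted keys.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "otsu": {
        "t1_range": [1, 50],
        "t2_max": 150,
        "smooth": True,
    },
    "morph": {
        "open_factor": 0.3,
        "close_factor": 0.7,
    },
    "locate": {
        "min_run": 1,
    },
    "crrl": {
        "n_rays": 36,
        "delta_coeff": 1.4,
        "inner": 0.5,
        "outer": 1.5,
        "step": 0.5,
        "band": False,
        # scale mapping the intensity-domain threshold 1.4*(T2-T1) onto the
        # gradient amplitude of a blurred edge (see CrrlParams docstring)
        "delta_scale": 0.25,
        "count_coeff": 0.8,
        "max_width": 6.0,
        "use_smoothed": False,
    },
    "fit": {
        "min_points": 6,
        "cond_limit": 1e12,
    },
    "glint": {
        "threshold": 240,
        "min_area": 4,
        "max_area": 400,
        "expected_count": 4,
        "floor_frac": 0.2,
        "halo": 2,
    },
    "eval": {
        "success_radius": 5.0,
        "glint_match_radius": 3.0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Return DEFAULTS, deep-merged with the YAML file at ``path`` if given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    text = Path(path).read_text()
    override = yaml.safe_load(text) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(DEFAULTS, override)


def get(cfg: dict, dotted: str):
    """``get(cfg, "otsu.t2_max")`` → ``cfg["otsu"]["t2_max"]``."""
    node = cfg
    for part in dotted.split("."):
        node = node[part]
    return node
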