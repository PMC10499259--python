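"""Pipeline configuration: defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {
        "n_subjects": 24,
        "n_male": 10,
        "effects": "null",        # null | moderate | strong | explicit mapping
        "dropped_trials": "default",
        "overrides": {},          # GEN_DEFAULTS overrides
    },
    "extraction": {
        "marker_cutoff_hz": 10.0,
        "force_cutoff_hz": 20.0,
        "standing_window_s": 30.0,
        "offload_guard_s": 5.0,
        "cop_bandwidth_m": 0.02,
        "contact_threshold_n": 20.0,
        "max_gap_frames": 100,
    },
    "stats": {
        "n_perm": 10_000,
        "n_perm_pairwise": 1_000,
        "alpha": 0.05,
        "pairwise": False,
        "two_way": False,
    },
    "classify": {
        "test_fraction": 0.2,
        "models": {},
    },
    "output_dir": "results/pipeline",
}

DEMO_CONFIG_OVERRIDES: dict = {
    "generator": {
        "n_subjects": 6,
        "n_male": 3,
        "effects": "strong",
        "dropped_trials": None,
        "overrides": {"standing_duration": 16.0},
    },
    "extraction": {"standing_window_s": 10.0},
    "stats": {"n_perm": 500},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = deepcopy(v)
    return out


def default_config() -> dict:
    return deepcopy(DEFAULT_CONFIG)


def demo_config() -> dict:
    """Small end-to-end configuration (6 subjects, 500 permutations)."""
    return _deep_merge(DEFAULT_CONFIG, DEMO_CONFIG_OVERRIDES)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
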