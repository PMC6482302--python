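"""Pipeline configuration: defaults, YAML loading, schema validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULT_CONFIG: dict = {
    "synth": {
        "counts": {"relaxed": 43, "happy": 21, "sad": 18, "angry": 14},
        "segment_seconds": 150.0,
        "rate": 2000.0,
        "snr_db": 20.0,
    },
    "preprocess": {
        "cutoff_hz": 200.0,
        "order": 4,
        "envelope_window_s": 0.02,
    },
    "preselect": {
        "min_periodicity": 0.2,
        "period_lo_s": 0.3,
        "period_hi_s": 1.5,
        "max_noise_fraction": 0.25,
        "noise_band_hz": 400.0,
        "max_clip_fraction": 1e-3,
    },
    "segment": {
        "lobe_threshold": 0.10,
        "boundary_fraction": 0.10,
        "min_lobe_s": 0.02,
        "merge_gap_s": 0.02,
        "refine": True,
    },
    "features": {
        "m_max": 22,
    },
    "classify": {
        "tasks": ["valence", "arousal", "four_class"],
        "n_runs": 30,
        "weight_threshold": 0.5,
        "folds": 5,
        "ga": {
            "population": 30,
            "generations": 50,
            "crossover_prob": 0.7,
            "mutation_prob": None,
            "tournament_size": 3,
            "init_prob": 0.5,
        },
        "grid": {
            "log2c": [-5, 15, 2],
            "log2g": [-15, 3, 2],
        },
    },
    "seed": 0,
}


def _validate(cfg: dict, schema: dict, path: str = "") -> None:
    for key, value in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown config key: {path}{key}")
        ref = schema[key]
        if isinstance(ref, dict) and isinstance(value, dict):
            _validate(value, ref, path=f"{path}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Resolve the pipeline config: defaults <- YAML file <- overrides.

    Unknown keys anywhere are rejected.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        _validate(loaded, DEFAULT_CONFIG)
        cfg = _merge(cfg, loaded)
    if overrides:
        _validate(overrides, DEFAULT_CONFIG)
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
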