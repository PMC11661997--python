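"""Run configuration: a flat key-value file mapped onto Params.

The config file is YAML restricted to one flat mapping (no nesting
needed: split parameters are plain keys with a ``split_`` prefix).
Command-line flags override file values; every run logs the fully
resolved parameter set into its report for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .builder import Params
from .segmentation import SplitConfig

_PARAM_KEYS = {
    "k": int,
    "s_d": float,
    "f": float,
    "depth_b": int,
    "s_eqc": float,
    "d": float,
    "max_cost": float,
    "hull_resolution": float,
    "interpolation": str,
    "normalize_ground": bool,
    "time_scale": float,
    "value_scale": float,
    "greedy": bool,
}

_SPLIT_KEYS = {
    "split_mode": ("mode", str),
    "split_segment_length": ("segment_length", float),
    "split_remainder_threshold": ("remainder_threshold", float),
    "split_window": ("window", float),
    "split_step": ("step", float),
    "split_n_segments": ("n_segments", int),
    "split_boundaries": ("boundaries", list),
}


@dataclass
class RunConfig:
    """Parameters plus I/O locations for one CLI run."""

    params: Params = field(default_factory=Params)
    input_glob: str = "*.csv"
    output_dir: str = "out"
    seed: int = 0

    def to_flat_dict(self) -> dict[str, Any]:
        flat: dict[str, Any] = {
            k: getattr(self.params, k)
            for k in _PARAM_KEYS
            if getattr(self.params, k) is not None
        }
        split = self.params.split
        flat["split_mode"] = split.mode
        if split.mode == "fixed":
            flat["split_segment_length"] = split.segment_length
            flat["split_remainder_threshold"] = split.remainder_threshold
        elif split.mode == "windowed":
            flat["split_window"] = split.window
            flat["split_step"] = split.step
            flat["split_n_segments"] = split.n_segments
        elif split.mode == "manual":
            flat["split_boundaries"] = [list(b) for b in split.boundaries]
        flat["input_glob"] = self.input_glob
        flat["output_dir"] = self.output_dir
        flat["seed"] = self.seed
        return flat


def config_from_flat(flat: dict[str, Any]) -> RunConfig:
    param_kwargs: dict[str, Any] = {}
    split_kwargs: dict[str, Any] = {}
    for key, value in flat.items():
        if key in _PARAM_KEYS:
            param_kwargs[key] = _PARAM_KEYS[key](value) if value is not None else None
        elif key in _SPLIT_KEYS:
            name, cast = _SPLIT_KEYS[key]
            if name == "boundaries":
                split_kwargs[name] = [tuple(map(float, b)) for b in value]
            else:
                split_kwargs[name] = cast(value)
        elif key not in ("input_glob", "output_dir", "seed"):
            raise ValueError(f"unknown configuration key {key!r}")
    params = Params(split=SplitConfig(**split_kwargs), **param_kwargs)
    return RunConfig(
        params=params,
        input_glob=str(flat.get("input_glob", "*.csv")),
        output_dir=str(flat.get("output_dir", "out")),
        seed=int(flat.get("seed", 0)),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        flat = yaml.safe_load(fh) or {}
    if not isinstance(flat, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return config_from_flat(flat)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=True)
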