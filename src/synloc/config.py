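"""Single YAML configuration schema shared by all pipeline stages."""

from __future__ import annotations

from copy import deepcopy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config"]

#: Defaults for every stage; a user config file overrides keys selectively.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "voxel_size_um": [0.4, 0.2, 0.2],
    "channels": {"rgfp": 0, "membrane": 1, "brp": 2},
    # the library default censors only voxels literally devoid of membrane
    # signal (fixed threshold 0); the pipeline default resolves a positive
    # threshold from the histogram, which is the sane choice on noisy data
    "mask": {"method": "otsu", "threshold": 0.0},
    "li": {"winsorize_quantile": None, "statistic": "mean"},
    "render": {
        "colormap": "coolwarm",
        "li_range": [0.5, 2.0],
        "intensity_gamma": 1.0,
        "projection": "max_intensity",
    },
    "puncta": {
        "sigma_range_um": [0.2, 0.45],
        "peak_threshold": 8.0,
        "theta_overlap": 0.5,
        "theta_adj": "auto",
        "auto_k": 2.0,
    },
    "stats": {"alpha": 0.05, "homoscedasticity": "bartlett", "post_hoc": "auto"},
    "behavior": {"window_seconds": 60, "sign": "aversive"},
    "synthetic": {},  # overrides for NeuronVolumeParams fields
}


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` into ``base`` (returns a new dict)."""
    out = deepcopy(dict(base))
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the package defaults."""
    if path is None:
        return deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return merge_config(DEFAULT_CONFIG, user)
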