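"""Configuration loading and round-trip serialization.

All tunable constants of the model live in a single nested-mapping
parameter file (YAML).  The package ships a default file
(``evoplankton/data/default_params.yaml``); user files are deep-merged on
top of it, so a file needs to contain only the keys it overrides.
"""

from __future__ import annotations

import copy
import importlib.resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["default_params", "load_params", "save_params", "deep_merge"]


def _default_path():
    return importlib.resources.files("evoplankton.data") / "default_params.yaml"


def default_params() -> dict[str, Any]:
    """Return a fresh copy of the packaged default parameter tree."""
    with _default_path().open("r") as fh:
        return yaml.safe_load(fh)


def deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` into ``base`` (non-destructive)."""
    out = copy.deepcopy(dict(base))
    for key, val in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(val, Mapping):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_params(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load a parameter tree: defaults <- file (optional) <- overrides (optional)."""
    params = default_params()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        params = deep_merge(params, user)
    if overrides:
        params = deep_merge(params, overrides)
    return params


def save_params(params: Mapping[str, Any], path: str | Path) -> None:
    """Write a parameter tree to YAML.  ``load_params(path)`` restores it
    losslessly (YAML scalars round-trip exactly; floats are emitted with
    full repr precision)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(params), fh, sort_keys=False, default_flow_style=None)
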