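"""Configuration loading: flat YAML key-value files plus flag overrides."""

from __future__ import annotations

from pathlib import Path

import yaml

from .params import GROUP_SIZE_PRESETS, SimParams

__all__ = ["load_config"]


def load_config(path: str | Path | None = None, **overrides) -> SimParams:
    """Build :class:`SimParams` from an optional config file and overrides.

    The file is flat YAML whose keys mirror the SimParams fields (r, d, lam,
    K, f, mu, nu, c, burn_in, stop_recruits, seed, plus implementation
    variants).  A ``preset`` key ("small" | "intermediate" | "large") sets the
    recruitment rate to 0.03 / 0.06 / 0.2.  Keyword overrides win over file
    values; unknown keys are rejected; validation errors name the offending
    field.  An empty config yields the defaults.
    """
    merged: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat key-value mapping")
        merged.update(data)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    preset = merged.pop("preset", None)
    if preset is not None:
        if preset not in GROUP_SIZE_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; expected one of {sorted(GROUP_SIZE_PRESETS)}"
            )
        merged.setdefault("r", GROUP_SIZE_PRESETS[preset])
    return SimParams.from_dict(merged)
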