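"""Crop profile serialization and the packaged built-in profiles."""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any

import yaml

from cropsuit.errors import InputError
from cropsuit.fuzzy import CriterionProfile, CropProfile, FuzzySet

BUILTIN_PROFILES = ("breadfruit_final", "breadfruit_ecocrop")

_THRESHOLD_KEYS = ("abs_min", "opt_min", "opt_max", "abs_max")


def profile_from_dict(data: dict[str, Any]) -> CropProfile:
    """Build a :class:`CropProfile` from a parsed config mapping."""
    try:
        label = data["label"]
        criteria_cfg = data["criteria"]
    except (KeyError, TypeError) as exc:
        raise InputError(f"profile config missing required key: {exc}") from exc
    criteria = []
    for name, cfg in criteria_cfg.items():
        missing = [k for k in _THRESHOLD_KEYS if k not in cfg]
        if missing:
            raise InputError(f"criterion {name!r} missing threshold(s) {missing}")
        fset = FuzzySet(*(float(cfg[k]) for k in _THRESHOLD_KEYS))
        criteria.append(CriterionProfile(name=name, units=str(cfg.get("units", "")), set=fset))
    return CropProfile(label=str(label), criteria=tuple(criteria))


def profile_to_dict(profile: CropProfile) -> dict[str, Any]:
    """Inverse of :func:`profile_from_dict`."""
    return {
        "label": profile.label,
        "criteria": {
            c.name: {
                "units": c.units,
                "abs_min": c.set.abs_min,
                "opt_min": c.set.opt_min,
                "opt_max": c.set.opt_max,
                "abs_max": c.set.abs_max,
            }
            for c in profile.criteria
        },
    }


def load_profile(path: str | Path) -> CropProfile:
    """Load a crop profile from a YAML (or JSON — a YAML subset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return profile_from_dict(data)


def save_profile(profile: CropProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(profile_to_dict(profile), fh, sort_keys=False)


def builtin_profile(name: str) -> CropProfile:
    """Return one of the packaged profiles (``breadfruit_final``, ``breadfruit_ecocrop``)."""
    if name not in BUILTIN_PROFILES:
        raise InputError(f"unknown built-in profile {name!r}; choose from {BUILTIN_PROFILES}")
    ref = importlib.resources.files(__package__) / f"{name}.yaml"
    data = yaml.safe_load(ref.read_text())
    return profile_from_dict(data)


def resolve_profile(spec: str) -> CropProfile:
    """Interpret ``spec`` as a built-in profile name or a config file path."""
    if spec in BUILTIN_PROFILES:
        return builtin_profile(spec)
    if Path(spec).exists():
        return load_profile(spec)
    raise InputError(f"profile {spec!r} is neither a built-in name nor an existing file")
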