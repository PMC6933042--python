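"""Bundled fixtures: phantom specs, system profiles, reference MAD tables."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from ..phantom_geometry import PhantomSpec
from ..simulator import SystemProfile

__all__ = [
    "available_phantoms",
    "load_phantom",
    "available_profile_modes",
    "load_profiles",
    "load_reference_intersystem_mad",
    "load_schema",
]

PROFILE_MODES = ("vendor-specific", "vendor-neutral")


def _root():
    return resources.files(__package__)


def available_phantoms() -> list[str]:
    return sorted(p.name[: -len(".json")] for p in (_root() / "phantoms").iterdir()
                  if p.name.endswith(".json"))


def load_phantom(name: str) -> PhantomSpec:
    path = _root() / "phantoms" / f"{name}.json"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown phantom {name!r}; available: {available_phantoms()}") from None
    return PhantomSpec.model_validate_json(text)


def available_profile_modes() -> tuple[str, ...]:
    return PROFILE_MODES


def load_profiles(mode: str = "vendor-specific") -> list[SystemProfile]:
    """The five bundled system profiles for one reconstruction mode.

    ``vendor-specific`` profiles are heterogeneous (per-system
    post-filters, voxel sizes and synthetic calibration biases);
    ``vendor-neutral`` profiles share one post-filter, voxel size and an
    unbiased calibration, emulating a common third-party reconstruction.
    """
    if mode not in PROFILE_MODES:
        raise KeyError(f"unknown profile mode {mode!r}; available: {PROFILE_MODES}")
    sub = "vendor_specific" if mode == "vendor-specific" else "vendor_neutral"
    profiles = []
    for p in sorted((_root() / "profiles" / sub).iterdir(), key=lambda p: p.name):
        if p.name.endswith(".json"):
            profiles.append(SystemProfile.model_validate_json(p.read_text()))
    return profiles


def load_reference_intersystem_mad() -> pd.DataFrame:
    """Published per-sphere inter-system MADs from a five-system multi-center
    Tc-99m SPECT/CT phantom comparison, for vendor-specific and
    vendor-neutral reconstructions (columns: sphere_diameter_mm, metric,
    reconstruction, mad)."""
    with resources.as_file(_root() / "reference" / "intersystem_mad_reference.csv") as f:
        return pd.read_csv(f)


def load_schema(name: str) -> dict:
    """A bundled JSON schema: 'phantom_spec', 'system_profile' or
    'experiment_config'."""
    path = _root() / "schemas" / f"{name}.schema.json"
    try:
        return json.loads(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown schema {name!r}") from None
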