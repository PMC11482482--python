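"""Structured-text (YAML) configuration for case runs.

A config file has optional sections ``needle``, ``domain``, ``grid``, ``em``,
``thermal``, ``damage`` whose keys mirror the dataclass fields, plus a
``materials`` mapping of symbol_material overrides (``sigma_liver``,
``Cp_tumor``, ``omega_blood``, ``T_blood``, ...) matching the parameter-table
naming.  Unspecified values fall back to the case defaults (phantom or
clinical).  Decimal-representable values round-trip exactly.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import yaml

from . import bioheat, damage, em, geometry
from .materials import BloodProperties
from .pipeline import CaseConfig

__all__ = ["load_config", "save_config", "config_from_dict", "config_to_dict"]

_SECTIONS = {
    "needle": geometry.NeedleSpec,
    "domain": geometry.DomainSpec,
    "grid": geometry.GridPolicy,
    "em": em.EMConfig,
    "thermal": bioheat.ThermalConfig,
    "damage": damage.DamageParams,
}
_ATTR = {"needle": "needle", "domain": "domain", "grid": "grid_policy",
         "em": "em", "thermal": "thermal", "damage": "damage"}


def config_from_dict(data: dict) -> CaseConfig:
    case = data.get("case", data.get("case_kind", "phantom"))
    base = CaseConfig.phantom() if case == "phantom" else CaseConfig.clinical()
    updates: dict = {}
    for section, cls in _SECTIONS.items():
        if section not in data:
            continue
        sect = dict(data[section])
        if section == "thermal" and "blood" in sect:
            sect["blood"] = BloodProperties(**sect["blood"])
        if section == "grid" and "cells_per_layer" in sect:
            sect["cells_per_layer"] = tuple(sect["cells_per_layer"])
        current = getattr(base, _ATTR[section])
        unknown = set(sect) - set(vars(current))
        if unknown:
            raise KeyError(f"unknown {section} config key(s): {sorted(unknown)}")
        updates[_ATTR[section]] = replace(current, **sect)
    if "materials" in data:
        updates["material_overrides"] = dict(data["materials"])
    for scalar in ("voxel_spacing", "seed"):
        if scalar in data:
            updates[scalar] = data[scalar]
    return replace(base, **updates)


def config_to_dict(config: CaseConfig) -> dict:
    out = {"case": config.case_kind}
    for section, attr in _ATTR.items():
        d = asdict(getattr(config, attr))
        if section == "grid":
            d["cells_per_layer"] = list(d["cells_per_layer"])
        out[section] = d
    out["materials"] = dict(config.material_overrides)
    out["voxel_spacing"] = config.voxel_spacing
    out["seed"] = config.seed
    return out


def load_config(path: str | Path) -> CaseConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: CaseConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
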