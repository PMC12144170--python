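"""YAML/JSON case-configuration loading.

A config selects a shipped case by name and may override any construct,
load, zone-threshold or calibration parameter; the shipped YAML files under
``fracturetwin/configs/`` spell out every default so they double as the
schema documentation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .cases import CaseDefinition, LoadSpec, build_case
from .materials import DensityCalibration
from .mechanobiology import HealingZoneConfig
from .synthetic import (
    ConstructSpec,
    PlateSpec,
    ProminenceSpec,
    ScrewSpec,
    WristParams,
)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _apply_overrides(obj, overrides: dict | None):
    if not overrides:
        return obj
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        if key not in valid:
            raise ValueError(
                f"unknown field {key!r} for {type(obj).__name__}; "
                f"valid fields: {sorted(valid)}"
            )
        current = getattr(obj, key)
        if key == "plate" and isinstance(value, dict):
            screws = [ScrewSpec(**s) for s in value.pop("plate_screws", [])]
            value = PlateSpec(**value, plate_screws=screws)
        elif key == "screws" and isinstance(value, list):
            value = [ScrewSpec(**s) if isinstance(s, dict) else s for s in value]
        elif key == "prominence" and isinstance(value, dict):
            value = ProminenceSpec(**value)
        elif isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            merged.update(value)
            value = merged
        setattr(obj, key, value)
    return obj


def case_from_config(cfg: dict, seed: int | None = None) -> CaseDefinition:
    """Build a CaseDefinition from a parsed config mapping."""
    name = cfg.get("case", "usecase1_nail_diameter")
    desk_scale = bool(cfg.get("desk_scale", True))
    if seed is None:
        seed = int(cfg.get("seed", 0))
    case = build_case(name, seed=seed, desk_scale=desk_scale)
    case.element_order = int(cfg.get("element_order", case.element_order))
    if isinstance(case.baseline, WristParams):
        _apply_overrides(case.baseline, cfg.get("baseline"))
        _apply_overrides(case.revision, cfg.get("revision"))
        rom = cfg.get("rom") or {}
        if "range" in rom:
            case.rom_range = tuple(float(v) for v in rom["range"])
        if "step" in rom:
            case.rom_step = float(rom["step"])
        return case
    _apply_overrides(case.baseline, cfg.get("baseline"))
    _apply_overrides(case.revision, cfg.get("revision"))
    case.baseline.seed = seed
    case.revision.seed = seed
    _apply_overrides(case.load, cfg.get("load"))
    _apply_overrides(case.zones, cfg.get("zones"))
    _apply_overrides(case.calibration, cfg.get("calibration"))
    return case


def shipped_config_path(name: str) -> Path:
    short = {
        "usecase1_nail_diameter": "usecase1",
        "usecase2_plate_humerus_analogue": "usecase2",
        "usecase3_plate_femur_analogue": "usecase3",
        "usecase4_screw_torsion": "usecase4",
        "usecase5_wrist": "usecase5",
    }.get(name, name)
    return Path(__file__).parent / "configs" / f"{short}.yaml"
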