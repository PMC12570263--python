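"""Nested configuration handling: load/save, validation, dotted paths.

The configuration is a plain nested dict (YAML on disk). Validation is
structural against the packaged baseline template: unknown keys are hard
errors so a typo cannot silently leave a parameter at its default.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Iterator

import yaml

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "get_path",
    "set_path",
    "iter_leaf_paths",
    "validate_config",
    "config_hash",
    "build_specs",
]


class ConfigError(ValueError):
    """Schema-invalid configuration; carries the failing path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("<root>", "configuration must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def get_path(cfg: dict, dotted: str) -> Any:
    node: Any = cfg
    for key in dotted.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(dotted, "path not found")
        node = node[key]
    return node


def set_path(cfg: dict, dotted: str, value: Any) -> None:
    keys = dotted.split(".")
    node: Any = cfg
    for key in keys[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(dotted, "path not found")
        node = node[key]
    if not isinstance(node, dict) or keys[-1] not in node:
        raise ConfigError(dotted, "path not found")
    node[keys[-1]] = value


def iter_leaf_paths(cfg: dict, prefix: str = "") -> Iterator[str]:
    for key, value in cfg.items():
        path = f"{prefix}.{key}" if prefix else str(key)
        if isinstance(value, dict):
            yield from iter_leaf_paths(value, path)
        else:
            yield path


def validate_config(cfg: dict, template: dict, _prefix: str = "") -> None:
    """Structural validation: same keys as the template, unknown keys fatal."""
    for key in cfg:
        path = f"{_prefix}.{key}" if _prefix else str(key)
        if key not in template:
            raise ConfigError(path, "unknown key")
        if isinstance(template[key], dict):
            if not isinstance(cfg[key], dict):
                raise ConfigError(path, "expected a mapping")
            validate_config(cfg[key], template[key], path)
    for key in template:
        path = f"{_prefix}.{key}" if _prefix else str(key)
        if key not in cfg:
            raise ConfigError(path, "missing key")


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def apply_overrides(cfg: dict, overrides: dict[str, Any]) -> dict:
    """Copy ``cfg`` with dotted-path overrides applied."""
    out = copy.deepcopy(cfg)
    for path, value in overrides.items():
        set_path(out, path, value)
    return out


def build_specs(cfg: dict) -> dict[str, Any]:
    """Instantiate the flowsheet/solubility spec objects from a config."""
    from .flowsheet import FacilitySpec, FeedstockSpec, FermentationSpec, SeparationSpec
    from .solubility import DecarbModel, SoluteThermo

    fd = cfg["feedstock"]
    days = float(cfg["operation"]["days_per_year"])
    annual = float(fd["annual_feed_wet_t"])
    capacity_factor = float(cfg["operation"].get("capacity_factor", 1.0))
    feed = FeedstockSpec(
        feed_rate_wet_t_per_h=annual * capacity_factor / (days * 24.0),
        water=float(fd["water"]),
        sucrose=float(fd["sucrose"]),
        glucose=float(fd["glucose"]),
        fiber=float(fd["fiber"]),
        ash=float(fd["ash"]),
        extraction_efficiency=float(fd["extraction_efficiency"]),
    )
    fm = cfg["fermentation"]
    ferm = FermentationSpec(
        yield_fraction_of_theoretical=float(fm["yield_fraction_of_theoretical"]),
        titer_g_per_L=float(fm["titer_g_per_L"]),
        productivity_g_per_L_h=float(fm["productivity_g_per_L_h"]),
        citric_acid_yield_g_per_g=float(fm["citric_acid_yield_g_per_g"]),
        cell_mass_yield_g_per_g=float(fm["cell_mass_yield_g_per_g"]),
        acetate_cofeed_ratio=float(fm["acetate_cofeed_ratio"]),
        csl_loading_g_per_L=float(fm["csl_loading_g_per_L"]),
        dap_loading_g_per_L=float(fm["dap_loading_g_per_L"]),
        max_sugar_concentration_g_per_L=float(fm["max_sugar_concentration_g_per_L"]),
        max_vessel_volume_m3=float(fm["max_vessel_volume_m3"]),
        temperature_C=float(fm["temperature_C"]),
    )
    sp = cfg["separation"]
    sep = SeparationSpec(
        crystallizer_temperature_C=float(sp["crystallizer_temperature_C"]),
        dissolution_cap_C=float(sp["dissolution_cap_C"]),
        maintained_pH=float(sp["maintained_pH"]),
        baseline_pH=float(sp["baseline_pH"]),
        solids_removal_efficiency=float(sp["solids_removal_efficiency"]),
        crystal_retention_efficiency=float(sp["crystal_retention_efficiency"]),
        wet_solids_moisture=float(sp["wet_solids_moisture"]),
        wet_cake_moisture=float(sp["wet_cake_moisture"]),
        dryer_outlet_moisture=float(sp["dryer_outlet_moisture"]),
        dryer_efficiency=float(sp["dryer_efficiency"]),
    )
    fc = cfg["facilities"]
    fac = FacilitySpec(
        boiler_efficiency=float(fc["boiler_efficiency"]),
        turbogenerator_efficiency=float(fc["turbogenerator_efficiency"]),
        biogas_yield_m3_per_kg_cod=float(fc["biogas_yield_m3_per_kg_cod"]),
        methane_lhv_MJ_per_m3=float(fc["methane_lhv_MJ_per_m3"]),
        fiber_lhv_MJ_per_kg=float(fc["fiber_lhv_MJ_per_kg"]),
        sugar_lhv_MJ_per_kg=float(fc["sugar_lhv_MJ_per_kg"]),
        natural_gas_lhv_MJ_per_kg=float(fc["natural_gas_lhv_MJ_per_kg"]),
        water_latent_heat_MJ_per_kg=float(fc["water_latent_heat_MJ_per_kg"]),
        evaporator_effect_factor=float(fc["evaporator_effect_factor"]),
        parasitic_kwh_per_t_feed=float(fc["parasitic_kwh_per_t_feed"]),
        chilled_water_cop=float(fc["chilled_water_cop"]),
        csl_cod_kg_per_kg=float(fc["csl_cod_kg_per_kg"]),
    )
    sl = cfg["solubility"]
    thermo = SoluteThermo(
        melting_temperature_K=float(sl["melting_temperature_K"]),
        fusion_enthalpy_J_per_mol=float(sl["fusion_enthalpy_J_per_mol"]),
        van_laar_A=float(sl["van_laar_A"]),
    )
    decarb = DecarbModel(
        tuple((float(p), float(c)) for p, c in sl["decarb_anchors"])
    )
    return {
        "feedstock": feed,
        "fermentation": ferm,
        "separation": sep,
        "facility": fac,
        "thermo": thermo,
        "decarb": decarb,
    }
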