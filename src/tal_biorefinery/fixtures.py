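"""Synthetic fixtures: baseline configuration, solubility datasets, and
parameter-distribution tables.

The baseline configuration carries every design-basis value
(fermentation yield 40.5% of theoretical, titer 35.9 g/L, productivity
0.12 g/L/h, citric yield 0.094 g/g, decarboxylation 20.9 mol% at pH 2.10,
crystallization at 1 degC, 180 operating days, 620,540 wet t cane/y for
13,385 t TAL/y, cane at $34.50/wet t, 10% IRR over 30 years) together
with documented calibration defaults for everything else. Fixtures
regenerate deterministically from (parameters, seed); the whole test
suite runs on them without any external data.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import config as _config
from .solubility import SolubilityRecord, SoluteThermo, calibrated_tal_thermo, solubility_g_per_L
from .uncertainty import ParameterDistribution

__all__ = [
    "baseline_config",
    "synth_solubility",
    "synth_parameter_table",
    "FixtureManifest",
    "generate_fixture",
    "BASELINE_ANNUAL_TAL_T",
]

#: design-basis production capacity, metric tons TAL per year
BASELINE_ANNUAL_TAL_T = 13385.0

#: config paths whose defaults are calibrated rather than design-basis
#: values; acceptance tooling can distinguish exact from calibrated checks
CALIBRATED_PATHS = (
    "feedstock.water",
    "feedstock.sucrose",
    "feedstock.glucose",
    "feedstock.fiber",
    "feedstock.ash",
    "feedstock.extraction_efficiency",
    "fermentation.acetate_cofeed_ratio",
    "fermentation.cell_mass_yield_g_per_g",
    "solubility.fusion_enthalpy_J_per_mol",
    "solubility.van_laar_A",
    "capital.calibration_factor",
)

# anchor-cost calibration factor: fitted once so the baseline configuration
# prices TAL at the design-basis MPSP of $4.60/kg (see docs/methods.md)
_CAPITAL_CALIBRATION_FACTOR = 0.5877


def _template_config(thermo: SoluteThermo) -> dict:
    return {
        "feedstock": {
            "annual_feed_wet_t": 620540.0,
            "water": 0.70,
            "sucrose": 0.135,
            "glucose": 0.015,
            "fiber": 0.135,
            "ash": 0.015,
            "extraction_efficiency": 0.92,
        },
        "operation": {
            "days_per_year": 180.0,
            "capacity_factor": 1.0,
        },
        "fermentation": {
            "yield_fraction_of_theoretical": 0.405,
            "titer_g_per_L": 35.9,
            "productivity_g_per_L_h": 0.12,
            "citric_acid_yield_g_per_g": 0.094,
            "cell_mass_yield_g_per_g": 0.10,
            "acetate_cofeed_ratio": 0.0,  # calibrated below
            "csl_loading_g_per_L": 10.0,
            "dap_loading_g_per_L": 0.33,
            "max_sugar_concentration_g_per_L": 600.0,
            "max_vessel_volume_m3": 3000.0,
            "temperature_C": 30.0,
        },
        "separation": {
            "crystallizer_temperature_C": 1.0,
            "dissolution_cap_C": 93.0,
            "maintained_pH": 2.10,
            "baseline_pH": 2.10,
            "solids_removal_efficiency": 0.99,
            "crystal_retention_efficiency": 0.95,
            "wet_solids_moisture": 0.70,
            "wet_cake_moisture": 0.35,
            "dryer_outlet_moisture": 0.005,
            "dryer_efficiency": 0.85,
        },
        "solubility": {
            "melting_temperature_K": thermo.melting_temperature_K,
            "fusion_enthalpy_J_per_mol": thermo.fusion_enthalpy_J_per_mol,
            "van_laar_A": thermo.van_laar_A,
            "decarb_anchors": [[2.10, 0.209], [11.0, 0.048]],
        },
        "juicing": {
            "phosphoric_acid_g_per_L_juice": 0.6,
        },
        "facilities": {
            "boiler_efficiency": 0.80,
            "turbogenerator_efficiency": 0.28,
            "biogas_yield_m3_per_kg_cod": 0.30,
            "methane_lhv_MJ_per_m3": 35.8,
            "fiber_lhv_MJ_per_kg": 17.5,
            "sugar_lhv_MJ_per_kg": 15.6,
            "natural_gas_lhv_MJ_per_kg": 47.1,
            "water_latent_heat_MJ_per_kg": 2.26,
            "evaporator_effect_factor": 2.5,
            "parasitic_kwh_per_t_feed": 25.0,
            "chilled_water_cop": 3.5,
            "csl_cod_kg_per_kg": 1.0,
        },
        "finance": {
            "internal_rate_of_return": 0.10,
            "project_years": 30,
            "income_tax_rate": 0.21,
            "construction_schedule": [0.08, 0.60, 0.32],
            "depreciation_years": 10,
            "working_capital_fraction": 0.05,
            "fixed_opex_fraction_of_fci": 0.03,
            "fixed_opex_base_usd_per_y": 2.5e6,
        },
        "prices": {
            "sugarcane_usd_per_wet_t": 34.50,
            "sodium_acetate_usd_per_kg": 0.60,
            "naoh_usd_per_kg": 0.50,
            "csl_usd_per_kg": 0.08,
            "dap_usd_per_kg": 0.34,
            "phosphoric_acid_usd_per_kg": 0.70,
            # 2019 US industrial natural-gas price (~$4.1/MMBtu)
            "natural_gas_usd_per_kg": 0.218,
            "electricity_usd_per_kwh": 0.0685,
        },
        "capital": {
            "indirect_factor": 1.25,
            "calibration_factor": _CAPITAL_CALIBRATION_FACTOR,
            "units": {
                "juicing": {"anchor_cost_usd": 40e6, "anchor_size": 150.0, "exponent": 0.6, "installation_factor": 1.0},
                "conditioning": {"anchor_cost_usd": 5e6, "anchor_size": 150.0, "exponent": 0.6, "installation_factor": 1.0},
                "fermentation": {"anchor_cost_usd": 60e6, "anchor_size": 40000.0, "exponent": 0.6, "installation_factor": 1.0},
                "dissolution_hx": {"anchor_cost_usd": 2e6, "anchor_size": 20.0, "exponent": 0.6, "installation_factor": 1.0},
                "solids_centrifuge": {"anchor_cost_usd": 15e6, "anchor_size": 130.0, "exponent": 0.6, "installation_factor": 1.0},
                "crystallizer": {"anchor_cost_usd": 12e6, "anchor_size": 130.0, "exponent": 0.6, "installation_factor": 1.0},
                "crystal_centrifuge": {"anchor_cost_usd": 10e6, "anchor_size": 130.0, "exponent": 0.6, "installation_factor": 1.0},
                "dryer": {"anchor_cost_usd": 3e6, "anchor_size": 2.0, "exponent": 0.6, "installation_factor": 1.0},
                "boiler_turbogenerator": {"anchor_cost_usd": 45e6, "anchor_size": 450.0, "exponent": 0.6, "installation_factor": 1.0},
                "wastewater_treatment": {"anchor_cost_usd": 25e6, "anchor_size": 9.4, "exponent": 0.6, "installation_factor": 1.0},
                "storage_other": {"anchor_cost_usd": 5e6, "anchor_size": 150.0, "exponent": 0.6, "installation_factor": 1.0},
            },
        },
        "lca": {
            # characterization factors: documented placeholders standing in
            # for GREET-2022-sourced values (kg CO2-eq/kg and MJ/kg)
            "ci_factors": {
                "sugarcane": 0.085,
                "sodium_acetate": 1.40,
                "csl": 1.60,
                "dap": 1.60,
                "naoh": 1.20,
                "phosphoric_acid": 1.30,
                "natural_gas": 3.20,
            },
            "fec_factors": {
                "sugarcane": 1.10,
                "sodium_acetate": 28.0,
                "csl": 25.0,
                "dap": 24.0,
                "naoh": 20.0,
                "phosphoric_acid": 22.0,
                "natural_gas": 55.0,
            },
            "grid_ci_kg_co2e_per_kwh": 0.48,
            "grid_fec_MJ_per_kwh": 6.1,
            "dimedone_benchmark_ci": 8.0,
        },
        "market": {
            "sorbic_acid_price_range_usd_per_kg": [6.74, 8.71],
            "dimedone_replacement_price_usd_per_kg": 10.0,
            "sorbic_yield_g_per_g_tal": 0.889,
        },
    }


@lru_cache(maxsize=1)
def _baseline_config_cached() -> str:
    thermo = calibrated_tal_thermo()
    cfg = _template_config(thermo)

    # calibrate the sodium-acetate co-feed so the baseline lands exactly on
    # the design production capacity of 13,385 t TAL/y
    from .flowsheet import simulate  # deferred import (module cycle)

    def annual_gap(ratio: float) -> float:
        trial = copy.deepcopy(cfg)
        trial["fermentation"]["acetate_cofeed_ratio"] = ratio
        return simulate(trial).annual_tal_t - BASELINE_ANNUAL_TAL_T

    ratio = brentq(annual_gap, 0.0, 2.0, xtol=1e-10)
    cfg["fermentation"]["acetate_cofeed_ratio"] = ratio
    return json.dumps(cfg)


def baseline_config() -> dict:
    """The baseline biorefinery configuration (a fresh copy per call)."""
    return json.loads(_baseline_config_cached())


def synth_solubility(
    thermo: SoluteThermo | None = None,
    n: int = 12,
    noise_sd_fraction: float = 0.03,
    seed: int = 20250501,
) -> list[SolubilityRecord]:
    """Synthetic (T, g/L) solubility measurements over 0-93 degC.

    Temperatures are evenly spaced; values are model solubilities with
    multiplicative Gaussian noise, emulating the structure (n = 12, minimum
    near 3.52 g/L, maximum near 130.65 g/L) of the measured dataset.
    """
    if n < 2:
        raise ValueError("need n >= 2 points")
    if noise_sd_fraction < 0:
        raise ValueError("noise sd fraction must be non-negative")
    thermo = thermo or calibrated_tal_thermo()
    rng = np.random.default_rng(seed)
    temps = np.linspace(0.0, 93.0, n)
    out = []
    for t in temps:
        s = solubility_g_per_L(float(t), thermo)
        s_noisy = s * (1.0 + noise_sd_fraction * rng.standard_normal())
        out.append(SolubilityRecord(float(t), float(max(s_noisy, 1e-6))))
    return out


def synth_parameter_table(p: int = 30, seed: int = 20250501) -> list[ParameterDistribution]:
    """A 30-parameter uncertainty table attached to real config paths.

    Shapes follow the baseline-as-mode convention: triangular for process
    parameters, uniform for prices. A documented stand-in for a measured
    parameter-uncertainty table.
    """
    if p < 1:
        raise ValueError("need p >= 1 parameters")
    cfg = baseline_config()

    def tri(path, rel_lo, rel_hi):
        base = _config.get_path(cfg, path)
        return ParameterDistribution(
            name=path.split(".")[-1], shape="triangular",
            lower=base * rel_lo, upper=base * rel_hi, mode=base,
            baseline=base, path=path,
        )

    def uni(path, rel_lo, rel_hi):
        base = _config.get_path(cfg, path)
        return ParameterDistribution(
            name=path.split(".")[-1], shape="uniform",
            lower=base * rel_lo, upper=base * rel_hi, mode=None,
            baseline=base, path=path,
        )

    dists = [
        tri("fermentation.yield_fraction_of_theoretical", 0.8, 1.2),
        tri("fermentation.titer_g_per_L", 0.8, 1.2),
        tri("fermentation.productivity_g_per_L_h", 0.5, 1.5),
        tri("fermentation.citric_acid_yield_g_per_g", 0.8, 1.2),
        tri("fermentation.cell_mass_yield_g_per_g", 0.8, 1.2),
        tri("fermentation.acetate_cofeed_ratio", 0.9, 1.1),
        tri("fermentation.csl_loading_g_per_L", 0.8, 1.2),
        tri("fermentation.dap_loading_g_per_L", 0.8, 1.2),
        tri("feedstock.extraction_efficiency", 0.97, 1.02),
        uni("operation.days_per_year", 0.667, 1.111),  # 120-200 d
        tri("separation.solids_removal_efficiency", 0.97, 1.01),
        tri("separation.crystal_retention_efficiency", 0.95, 1.05),
        tri("separation.crystallizer_temperature_C", 0.5, 4.0),
        tri("separation.wet_cake_moisture", 0.8, 1.2),
        tri("separation.dryer_efficiency", 0.9, 1.1),
        tri("solubility.fusion_enthalpy_J_per_mol", 0.97, 1.03),
        tri("solubility.van_laar_A", 0.95, 1.05),
        tri("facilities.boiler_efficiency", 0.94, 1.06),
        tri("facilities.turbogenerator_efficiency", 0.85, 1.1),
        tri("facilities.biogas_yield_m3_per_kg_cod", 0.8, 1.2),
        tri("facilities.parasitic_kwh_per_t_feed", 0.8, 1.2),
        uni("prices.sugarcane_usd_per_wet_t", 0.8, 1.2),
        uni("prices.sodium_acetate_usd_per_kg", 0.8, 1.2),
        uni("prices.naoh_usd_per_kg", 0.8, 1.2),
        uni("prices.csl_usd_per_kg", 0.8, 1.2),
        uni("prices.dap_usd_per_kg", 0.8, 1.2),
        uni("prices.natural_gas_usd_per_kg", 0.8, 1.2),
        uni("prices.electricity_usd_per_kwh", 0.8, 1.2),
        tri("finance.income_tax_rate", 0.9, 1.1),
        tri("finance.internal_rate_of_return", 0.9, 1.1),
    ]
    if p > len(dists):
        raise ValueError(f"at most {len(dists)} packaged parameters available")
    return dists[:p]


@dataclass
class FixtureManifest:
    """Record sufficient to regenerate a fixture byte-identically."""

    name: str
    seed: int
    generation_parameters: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "seed": self.seed,
                "generation_parameters": self.generation_parameters,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )


def generate_fixture(name: str, out_dir: str | Path, seed: int = 20250501) -> FixtureManifest:
    """Write the named fixture (config + CSVs + manifest) to ``out_dir``."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name != "baseline":
        raise ValueError(f"unknown fixture {name!r}")
    cfg = baseline_config()
    _config.save_config(cfg, out / "config.yaml")
    records = synth_solubility(seed=seed)
    pd.DataFrame(records, columns=["temperature_C", "solubility_g_per_L"]).to_csv(
        out / "solubility.csv", index=False
    )
    dists = synth_parameter_table(seed=seed)
    pd.DataFrame(
        [
            {
                "name": d.name, "shape": d.shape, "lower": d.lower,
                "mode": d.mode, "upper": d.upper, "baseline": d.baseline,
                "path": d.path,
            }
            for d in dists
        ]
    ).to_csv(out / "parameters.csv", index=False)
    manifest = FixtureManifest(
        name=name,
        seed=seed,
        generation_parameters={"n_solubility": 12, "noise_sd_fraction": 0.03, "p": 30},
        files=["config.yaml", "solubility.csv", "parameters.csv"],
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
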