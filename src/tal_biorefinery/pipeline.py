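"""Config-to-indicator evaluation: the single entry point used by the CLI,
Monte Carlo driver, scenario runner and grid maps.

``evaluate(config)`` runs the flowsheet simulation, solves the MPSP, and
performs the LCA, returning the three sustainability indicators the analysis
tracks (MPSP in $/kg, CI in kg CO2-eq/kg, FEC in MJ/kg).
"""

from __future__ import annotations

from typing import Any

from . import lca as _lca
from . import tea as _tea
from .flowsheet import SystemResult, simulate

__all__ = [
    "build_finance",
    "build_prices",
    "build_cost_model",
    "build_impact_factors",
    "evaluate",
]


def build_finance(cfg: dict) -> _tea.FinanceSpec:
    f = cfg["finance"]
    return _tea.FinanceSpec(
        internal_rate_of_return=float(f["internal_rate_of_return"]),
        project_years=int(f["project_years"]),
        income_tax_rate=float(f["income_tax_rate"]),
        construction_schedule=tuple(float(x) for x in f["construction_schedule"]),
        depreciation_years=int(f["depreciation_years"]),
        working_capital_fraction=float(f["working_capital_fraction"]),
        fixed_opex_fraction_of_fci=float(f["fixed_opex_fraction_of_fci"]),
        fixed_opex_base_usd_per_y=float(f["fixed_opex_base_usd_per_y"]),
    )


def build_prices(cfg: dict) -> _tea.PriceSet:
    p = cfg["prices"]
    return _tea.PriceSet(
        sugarcane_usd_per_wet_t=float(p["sugarcane_usd_per_wet_t"]),
        sodium_acetate_usd_per_kg=float(p["sodium_acetate_usd_per_kg"]),
        naoh_usd_per_kg=float(p["naoh_usd_per_kg"]),
        csl_usd_per_kg=float(p["csl_usd_per_kg"]),
        dap_usd_per_kg=float(p["dap_usd_per_kg"]),
        phosphoric_acid_usd_per_kg=float(p["phosphoric_acid_usd_per_kg"]),
        natural_gas_usd_per_kg=float(p["natural_gas_usd_per_kg"]),
        electricity_usd_per_kwh=float(p["electricity_usd_per_kwh"]),
    )


def build_cost_model(cfg: dict) -> _tea.CostModel:
    c = cfg["capital"]
    units = {
        name: _tea.UnitCost(
            anchor_cost_usd=float(u["anchor_cost_usd"]),
            anchor_size=float(u["anchor_size"]),
            exponent=float(u["exponent"]),
            installation_factor=float(u["installation_factor"]),
        )
        for name, u in c["units"].items()
    }
    return _tea.CostModel(
        units=units,
        indirect_factor=float(c["indirect_factor"]),
        calibration_factor=float(c["calibration_factor"]),
    )


def build_impact_factors(cfg: dict) -> _lca.ImpactFactorSet:
    l = cfg["lca"]
    return _lca.ImpactFactorSet(
        ci_factors={k: float(v) for k, v in l["ci_factors"].items()},
        fec_factors={k: float(v) for k, v in l["fec_factors"].items()},
        grid_ci_kg_co2e_per_kwh=float(l["grid_ci_kg_co2e_per_kwh"]),
        grid_fec_MJ_per_kwh=float(l["grid_fec_MJ_per_kwh"]),
        dimedone_benchmark_ci=float(l["dimedone_benchmark_ci"]),
    )


INDICATOR_KEYS = ("mpsp_usd_per_kg", "ci_kg_co2e_per_kg", "fec_MJ_per_kg")


def indicator_model(base_cfg: dict):
    """Callable {config_path: value} -> indicators, for the Monte Carlo driver."""
    from .config import apply_overrides

    def model(overrides: dict[str, float]) -> dict[str, float]:
        trial = apply_overrides(base_cfg, {k: float(v) for k, v in overrides.items()})
        out = evaluate(trial)
        return {k: out[k] for k in INDICATOR_KEYS}

    return model


def evaluate(cfg: dict, return_system: bool = False) -> dict[str, Any]:
    """Simulate the biorefinery and compute MPSP, CI and FEC for ``cfg``."""
    system = simulate(cfg)
    finance = build_finance(cfg)
    prices = build_prices(cfg)
    cost_model = build_cost_model(cfg)
    factors = build_impact_factors(cfg)
    mpsp = _tea.solve_mpsp(system, finance, prices, cost_model)
    res = _lca.assess(system, factors)
    out: dict[str, Any] = {
        "mpsp_usd_per_kg": mpsp,
        "ci_kg_co2e_per_kg": res.net_ci,
        "fec_MJ_per_kg": res.net_fec,
        "annual_tal_t": system.annual_tal_t,
    }
    if return_system:
        out["system"] = system
        out["lca"] = res
    return out
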