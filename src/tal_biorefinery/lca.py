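"""Cradle-to-grave LCA: carbon intensity (GWP100) and fossil energy demand.

The functional unit is 1 kg of produced TAL. Gross impacts sum the
upstream burdens of every purchased input plus end-of-life oxidation of
the product carbon to CO2; coproduced electricity earns a displacement
credit at average-grid factors. Biogenic CO2 (fermentation vent and
combustion of biomass-derived fuel) is carbon-neutral by the accounting
convention used here, and the feedstock factor excludes credit for fixed
carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import chem as _chem
from .flowsheet import SystemResult

__all__ = ["ImpactFactorSet", "LcaResult", "inventory", "carbon_intensity", "fossil_energy"]

#: kg CO2 per kg TAL on complete oxidation (from the packaged reaction)
END_OF_LIFE_CO2_PER_KG = _chem.theoretical_mass_yield(
    _chem.default_reactions()["tal_oxidation"]
)


@dataclass
class ImpactFactorSet:
    """Per-input characterization factors.

    ``ci_factors`` in kg CO2-eq per kg input (sugarcane per kg wet cane),
    ``fec_factors`` in MJ per kg input; grid factors per kWh.
    """

    ci_factors: dict[str, float]
    fec_factors: dict[str, float]
    grid_ci_kg_co2e_per_kwh: float = 0.48
    grid_fec_MJ_per_kwh: float = 6.1
    dimedone_benchmark_ci: float = 8.0

    def __post_init__(self) -> None:
        for name, value in self.fec_factors.items():
            if value < 0:
                raise ValueError(f"negative FEC factor for {name}")


@dataclass
class LcaResult:
    gross_ci: float = 0.0
    offset_ci: float = 0.0
    end_of_life_ci: float = 0.0
    net_ci: float = 0.0
    gross_fec: float = 0.0
    offset_fec: float = 0.0
    net_fec: float = 0.0
    ci_breakdown: dict[str, float] = field(default_factory=dict)
    fec_breakdown: dict[str, float] = field(default_factory=dict)


def inventory(system: SystemResult) -> dict[str, float]:
    """Per-kg-TAL inventory: input masses (kg/kg) and electricity (kWh/kg).

    Homogeneous of degree zero in plant scale: doubling all flows and the
    product leaves the inventory unchanged.
    """
    if system.annual_tal_kg <= 0:
        raise ValueError("zero product: per-kg inventory undefined")
    per_kg = {}
    for name, flow in system.material_purchases_kg_per_h.items():
        per_kg[name] = flow / system.product_tal_kg_per_h
    per_kg["electricity_exported_kwh"] = (
        system.electricity_exported_kwh_per_h / system.product_tal_kg_per_h
    )
    per_kg["electricity_purchased_kwh"] = (
        system.electricity_purchased_kwh_per_h / system.product_tal_kg_per_h
    )
    return per_kg


def _aggregate(inv: dict[str, float], factors: dict[str, float], label: str) -> dict[str, float]:
    out = {}
    for name, amount in inv.items():
        if name.startswith("electricity_"):
            continue
        if name not in factors:
            raise KeyError(f"missing {label} factor for input {name!r}")
        out[name] = amount * factors[name]
    return out


def carbon_intensity(
    inv: dict[str, float], factors: ImpactFactorSet, result: LcaResult | None = None
) -> LcaResult:
    """Fill the CI fields of an :class:`LcaResult` from a per-kg inventory."""
    res = result or LcaResult()
    breakdown = _aggregate(inv, factors.ci_factors, "CI")
    breakdown["purchased_electricity"] = (
        inv.get("electricity_purchased_kwh", 0.0) * factors.grid_ci_kg_co2e_per_kwh
    )
    eol = END_OF_LIFE_CO2_PER_KG
    breakdown["end_of_life"] = eol
    res.end_of_life_ci = eol
    res.gross_ci = sum(breakdown.values())
    res.offset_ci = -(
        inv.get("electricity_exported_kwh", 0.0) * factors.grid_ci_kg_co2e_per_kwh
    )
    res.net_ci = res.gross_ci + res.offset_ci
    res.ci_breakdown = breakdown
    return res


def fossil_energy(
    inv: dict[str, float], factors: ImpactFactorSet, result: LcaResult | None = None
) -> LcaResult:
    """Fill the FEC fields of an :class:`LcaResult` from a per-kg inventory."""
    res = result or LcaResult()
    breakdown = _aggregate(inv, factors.fec_factors, "FEC")
    breakdown["purchased_electricity"] = (
        inv.get("electricity_purchased_kwh", 0.0) * factors.grid_fec_MJ_per_kwh
    )
    res.gross_fec = sum(breakdown.values())
    res.offset_fec = -(
        inv.get("electricity_exported_kwh", 0.0) * factors.grid_fec_MJ_per_kwh
    )
    res.net_fec = res.gross_fec + res.offset_fec
    res.fec_breakdown = breakdown
    return res


def assess(system: SystemResult, factors: ImpactFactorSet) -> LcaResult:
    """Full CI + FEC assessment of a simulated system."""
    inv = inventory(system)
    res = carbon_intensity(inv, factors)
    return fossil_energy(inv, factors, res)
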