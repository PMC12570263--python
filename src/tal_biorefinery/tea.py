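"""Techno-economic analysis: costing, discounted cash flow, and MPSP.

The minimum product selling price (MPSP) is the product price at which the
project net present value is zero at the targeted internal rate of return
(here the discount rate of the DCF). Equipment costing uses power-law
scaling against per-class anchors: cost = anchor * (size/anchor_size)**n,
an nth-plant shortcut that preserves the analysis surface (deltas, maps,
rankings) the analysis interrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .flowsheet import SystemResult

__all__ = [
    "FinanceSpec",
    "PriceSet",
    "UnitCost",
    "CostModel",
    "MarketBenchmark",
    "capital_cost",
    "operating_cost",
    "npv",
    "solve_mpsp",
    "max_viable_price",
    "salt_to_acid_price",
]


@dataclass
class FinanceSpec:
    internal_rate_of_return: float = 0.10
    project_years: int = 30
    income_tax_rate: float = 0.21
    construction_schedule: tuple[float, ...] = (0.08, 0.60, 0.32)
    depreciation_years: int = 10
    working_capital_fraction: float = 0.05
    fixed_opex_fraction_of_fci: float = 0.03
    fixed_opex_base_usd_per_y: float = 2.5e6

    def __post_init__(self) -> None:
        if self.internal_rate_of_return <= 0:
            raise ValueError("IRR must be positive")
        if self.project_years < 1:
            raise ValueError("project_years must be >= 1")
        if self.depreciation_years > self.project_years:
            raise ValueError("depreciation longer than the project")


@dataclass
class PriceSet:
    """Per-unit purchase prices, 2019 USD."""

    sugarcane_usd_per_wet_t: float = 34.50
    sodium_acetate_usd_per_kg: float = 0.60
    naoh_usd_per_kg: float = 0.50
    csl_usd_per_kg: float = 0.08
    dap_usd_per_kg: float = 0.34
    phosphoric_acid_usd_per_kg: float = 0.70
    natural_gas_usd_per_kg: float = 0.218
    electricity_usd_per_kwh: float = 0.0685

    def per_kg(self, input_name: str) -> float:
        key = f"{input_name}_usd_per_kg"
        if not hasattr(self, key):
            raise KeyError(f"no price for purchased input {input_name!r}")
        value = getattr(self, key)
        if value < 0:
            raise ValueError(f"negative price for {input_name}")
        return value


@dataclass(frozen=True)
class UnitCost:
    anchor_cost_usd: float
    anchor_size: float
    exponent: float = 0.6
    installation_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.exponent <= 1.0):
            raise ValueError("scaling exponent must be in (0, 1]")
        if self.anchor_cost_usd <= 0 or self.anchor_size <= 0:
            raise ValueError("anchors must be positive")

    def cost(self, size: float) -> float:
        if size <= 0:
            return 0.0
        return (
            self.anchor_cost_usd
            * (size / self.anchor_size) ** self.exponent
            * self.installation_factor
        )


@dataclass
class CostModel:
    units: dict[str, UnitCost]
    indirect_factor: float = 1.25
    calibration_factor: float = 1.0


@dataclass
class MarketBenchmark:
    """Price benchmarks for TAL as an upgrading feedstock."""

    sorbic_acid_price_range: tuple[float, float] = (6.74, 8.71)
    dimedone_replacement_price: float = 10.0
    sorbic_yield_g_per_g: float = 0.889

    @property
    def max_viable_tal_range(self) -> tuple[float, float]:
        lo, hi = self.sorbic_acid_price_range
        return (
            max_viable_price(lo, self.sorbic_yield_g_per_g),
            max_viable_price(hi, self.sorbic_yield_g_per_g),
        )


def capital_cost(system: SystemResult, model: CostModel) -> dict[str, float]:
    """Fixed capital investment by power-law scaling of unit-class anchors.

    Returns a breakdown dict including ``direct`` and ``fci`` totals.
    Raises ``KeyError`` naming any sized unit without a cost class.
    """
    breakdown: dict[str, float] = {}
    for unit, size in system.unit_sizes.items():
        if unit not in model.units:
            raise KeyError(f"no cost class mapped for unit {unit!r}")
        breakdown[unit] = model.units[unit].cost(size) * model.calibration_factor
    direct = sum(breakdown.values())
    breakdown["direct"] = direct
    breakdown["fci"] = direct * model.indirect_factor
    return breakdown


def operating_cost(
    system: SystemResult,
    prices: PriceSet,
    fixed_cost_usd_per_y: float = 0.0,
) -> dict[str, float]:
    """Annual operating cost net of electricity sales, with a breakdown.

    Material flows are priced per kg except sugarcane (per wet metric ton).
    Raises ``KeyError`` naming any purchased input without a price.
    """
    hours = system.operating_hours
    breakdown: dict[str, float] = {}
    for name, flow_kg_per_h in system.material_purchases_kg_per_h.items():
        annual_kg = flow_kg_per_h * hours
        if name == "sugarcane":
            breakdown[name] = annual_kg / 1000.0 * prices.sugarcane_usd_per_wet_t
        else:
            breakdown[name] = annual_kg * prices.per_kg(name)
    breakdown["purchased_electricity"] = (
        system.electricity_purchased_kwh_per_h * hours * prices.electricity_usd_per_kwh
    )
    breakdown["fixed"] = fixed_cost_usd_per_y
    breakdown["electricity_revenue"] = -(
        system.electricity_exported_kwh_per_h * hours * prices.electricity_usd_per_kwh
    )
    breakdown["total"] = sum(
        v for k, v in breakdown.items() if k not in ("total",)
    )
    return breakdown


def npv(cashflows: list[float] | np.ndarray, rate: float) -> float:
    """Net present value of cashflows indexed from t = 0."""
    if rate <= -1.0:
        raise ValueError("discount rate must exceed -1")
    cf = np.asarray(cashflows, dtype=float)
    t = np.arange(cf.size)
    return float(np.sum(cf / (1.0 + rate) ** t))


def project_cashflows(
    price_usd_per_kg: float,
    system: SystemResult,
    finance: FinanceSpec,
    prices: PriceSet,
    model: CostModel,
) -> np.ndarray:
    """Annual after-tax cashflows: construction years then operating years."""
    cap = capital_cost(system, model)
    fci = cap["fci"]
    wc = finance.working_capital_fraction * fci
    fixed = finance.fixed_opex_base_usd_per_y + finance.fixed_opex_fraction_of_fci * fci
    opex = operating_cost(system, prices, fixed)["total"]
    revenue = price_usd_per_kg * system.annual_tal_kg

    n_con = len(finance.construction_schedule)
    n = n_con + finance.project_years
    cf = np.zeros(n)
    for i, frac in enumerate(finance.construction_schedule):
        cf[i] -= frac * fci
    cf[n_con - 1] -= wc  # working capital committed entering operation
    dep = fci / finance.depreciation_years
    for y in range(finance.project_years):
        t = n_con + y
        depreciation = dep if y < finance.depreciation_years else 0.0
        taxable = revenue - opex - depreciation
        tax = finance.income_tax_rate * max(0.0, taxable)
        cf[t] += revenue - opex - tax
    cf[-1] += wc  # working capital recovered
    return cf


def solve_mpsp(
    system: SystemResult,
    finance: FinanceSpec,
    prices: PriceSet,
    model: CostModel,
    price_bounds: tuple[float, float] = (0.01, 1000.0),
) -> float:
    """Product price at which the project NPV is zero at the target IRR."""
    if system.annual_tal_kg <= 0:
        raise ValueError("annual product must be positive to solve an MPSP")

    def f(price: float) -> float:
        return npv(
            project_cashflows(price, system, finance, prices, model),
            finance.internal_rate_of_return,
        )

    lo, hi = price_bounds
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"price bounds do not bracket NPV=0 (NPV({lo})={flo:.3g}, "
            f"NPV({hi})={fhi:.3g})"
        )
    return brentq(f, lo, hi, xtol=1e-8, rtol=1e-14)


def max_viable_price(downstream_price: float, conversion_yield: float) -> float:
    """Highest feedstock price compatible with a downstream product price."""
    if not (0.0 < conversion_yield <= 1.0):
        raise ValueError("conversion yield must be in (0, 1]")
    return downstream_price * conversion_yield


def salt_to_acid_price(
    salt_price: float, salt_molar_mass: float, acid_molar_mass: float
) -> float:
    """Per-kg acid-equivalent price of a salt listing at 1:1 molar conversion."""
    if salt_molar_mass <= 0 or acid_molar_mass <= 0:
        raise ValueError("molar masses must be positive")
    return salt_price * salt_molar_mass / acid_molar_mass
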