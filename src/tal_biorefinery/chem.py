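"""Chemical registry, element-balanced reactions, and theoretical yields.

Every conversion factor in the biorefinery model (fermentation yields,
end-of-life CO2, catalytic-upgrading benchmarks) is anchored to an
element-balanced stoichiometric reaction rather than a hard-coded number,
so the balance checks here propagate through the whole analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = [
    "ATOMIC_MASSES",
    "ChemicalSpec",
    "ReactionSpec",
    "UnknownElementError",
    "UnbalancedReactionError",
    "parse_formula",
    "molar_mass",
    "theoretical_mass_yield",
    "default_registry",
    "default_reactions",
]

# IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """An element symbol is not in the packaged atomic-mass table."""


class UnbalancedReactionError(ValueError):
    """A reaction does not conserve one or more elements."""

    def __init__(self, residuals: Mapping[str, Fraction]):
        self.residuals = dict(residuals)
        detail = ", ".join(f"{el}: {r}" for el, r in sorted(self.residuals.items()))
        super().__init__(f"reaction is not element-balanced (residuals {detail})")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C6H6O3"`` into ``{"C": 6, "H": 6, "O": 3}``.

    Mappings pass through after validation. Counts must be positive integers.
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            symbol, count = match.group(1), int(match.group(2) or 1)
            counts[symbol] = counts.get(symbol, 0) + count
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
    for symbol, count in counts.items():
        if symbol not in ATOMIC_MASSES:
            raise UnknownElementError(f"unknown element symbol {symbol!r}")
        if not isinstance(count, int) or count <= 0:
            raise ValueError(f"element count for {symbol} must be a positive integer")
    return counts


def molar_mass(formula: str | Mapping[str, int]) -> float:
    """Molar mass in g/mol from a formula string or element→count map."""
    counts = parse_formula(formula)
    return sum(ATOMIC_MASSES[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class ChemicalSpec:
    """A chemical species with an elemental formula and a process role."""

    name: str
    formula_str: str
    role: str = "utility"  # substrate | product | byproduct | utility

    def __post_init__(self) -> None:
        parse_formula(self.formula_str)  # validates

    @property
    def formula(self) -> dict[str, int]:
        return parse_formula(self.formula_str)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula_str)

    def mass_fraction(self, element: str) -> float:
        """Mass fraction of one element (0 if absent)."""
        n = self.formula.get(element, 0)
        return n * ATOMIC_MASSES[element] / self.molar_mass


@dataclass(frozen=True)
class ReactionSpec:
    """Signed-coefficient reaction over a set of chemicals.

    Coefficients are negative for consumed species, positive for produced
    ones, and are kept as exact integers (or Fractions) so that the
    element-balance check is exact.
    """

    stoichiometry: tuple[tuple[ChemicalSpec, Fraction], ...]
    basis_substrate: str
    basis_product: str

    @classmethod
    def from_dict(
        cls,
        stoich: Mapping[ChemicalSpec, int | Fraction],
        basis_substrate: str,
        basis_product: str,
    ) -> "ReactionSpec":
        terms = tuple((chem, Fraction(coef)) for chem, coef in stoich.items())
        return cls(terms, basis_substrate, basis_product)

    def coefficient(self, name: str) -> Fraction:
        for chem, coef in self.stoichiometry:
            if chem.name == name:
                return coef
        raise KeyError(name)

    def element_residuals(self) -> dict[str, Fraction]:
        """Net atoms of each element over the reaction (0 means balanced)."""
        residuals: dict[str, Fraction] = {}
        for chem, coef in self.stoichiometry:
            for el, n in chem.formula.items():
                residuals[el] = residuals.get(el, Fraction(0)) + coef * n
        return residuals

    def check_balanced(self) -> None:
        bad = {el: r for el, r in self.element_residuals().items() if r != 0}
        if bad:
            raise UnbalancedReactionError(bad)


def theoretical_mass_yield(reaction: ReactionSpec) -> float:
    """Mass of basis product per mass of basis substrate, from stoichiometry.

    Invariant to uniform scaling of the coefficients; raises
    :class:`UnbalancedReactionError` if any element does not conserve.
    """
    reaction.check_balanced()
    sub = prod = None
    c_sub = c_prod = Fraction(0)
    for chem, coef in reaction.stoichiometry:
        if chem.name == reaction.basis_substrate:
            sub, c_sub = chem, coef
        if chem.name == reaction.basis_product:
            prod, c_prod = chem, coef
    if sub is None or prod is None or c_sub == 0 or c_prod == 0:
        raise ValueError("basis substrate/product must appear with nonzero coefficients")
    return float(abs(c_prod) * prod.molar_mass / (abs(c_sub) * sub.molar_mass))


def default_registry() -> dict[str, ChemicalSpec]:
    """Chemicals used across the sugarcane-to-TAL system."""
    chems = [
        ChemicalSpec("tal", "C6H6O3", "product"),  # triacetic acid lactone
        ChemicalSpec("glucose", "C6H12O6", "substrate"),
        ChemicalSpec("sucrose", "C12H22O11", "substrate"),
        ChemicalSpec("acetic_acid", "C2H4O2", "substrate"),
        ChemicalSpec("sodium_acetate", "C2H3NaO2", "substrate"),
        ChemicalSpec("citric_acid", "C6H8O7", "byproduct"),
        ChemicalSpec("sorbic_acid", "C6H8O2", "product"),
        ChemicalSpec("potassium_sorbate", "C6H7KO2", "product"),
        ChemicalSpec("acetylacetone", "C5H8O2", "byproduct"),  # 2,4-pentanedione
        ChemicalSpec("cell_mass", "C5H9NO2", "byproduct"),
        ChemicalSpec("co2", "CO2", "utility"),
        ChemicalSpec("o2", "O2", "utility"),
        ChemicalSpec("h2", "H2", "utility"),
        ChemicalSpec("h2o", "H2O", "utility"),
        ChemicalSpec("naoh", "NaOH", "utility"),
        ChemicalSpec("phosphoric_acid", "H3PO4", "utility"),
        ChemicalSpec("dap", "N2H9PO4", "utility"),  # diammonium phosphate
        ChemicalSpec("methane", "CH4", "utility"),
    ]
    return {c.name: c for c in chems}


def default_reactions() -> dict[str, ReactionSpec]:
    """Element-balanced reactions behind every packaged yield.

    Oxygen/water closure species are carried explicitly so that balance
    checks stay exact integer arithmetic.
    """
    r = default_registry()
    F = Fraction
    reactions = {
        # Aerobic fermentation routes; cofactor turnover lumped into O2/H2O.
        "glucose_to_tal": ReactionSpec.from_dict(
            {r["glucose"]: F(-3), r["o2"]: F(-6), r["tal"]: F(2),
             r["co2"]: F(6), r["h2o"]: F(12)},
            "glucose", "tal"),
        "acetate_to_tal": ReactionSpec.from_dict(
            {r["acetic_acid"]: F(-9), r["o2"]: F(-6), r["tal"]: F(2),
             r["co2"]: F(6), r["h2o"]: F(12)},
            "acetic_acid", "tal"),
        "glucose_to_citric": ReactionSpec.from_dict(
            {r["glucose"]: F(-2), r["o2"]: F(-3), r["citric_acid"]: F(2),
             r["h2o"]: F(4)},
            "glucose", "citric_acid"),
        "sucrose_hydrolysis": ReactionSpec.from_dict(
            {r["sucrose"]: F(-1), r["h2o"]: F(-1), r["glucose"]: F(2)},
            "sucrose", "glucose"),
        # Net catalytic upgrading (hydrogenation-dehydration-ring-opening-hydrolysis).
        "tal_to_sorbic": ReactionSpec.from_dict(
            {r["tal"]: F(-1), r["h2"]: F(-2), r["sorbic_acid"]: F(1),
             r["h2o"]: F(1)},
            "tal", "sorbic_acid"),
        # Ring-opening decarboxylation of dissolved TAL to acetylacetone.
        "tal_decarboxylation": ReactionSpec.from_dict(
            {r["tal"]: F(-1), r["h2o"]: F(-1), r["acetylacetone"]: F(1),
             r["co2"]: F(1)},
            "tal", "acetylacetone"),
        # End-of-life passive oxidation of the product.
        "tal_oxidation": ReactionSpec.from_dict(
            {r["tal"]: F(-1), r["o2"]: F(-6), r["co2"]: F(6), r["h2o"]: F(3)},
            "tal", "co2"),
    }
    for rx in reactions.values():
        rx.check_balanced()
    return reactions
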