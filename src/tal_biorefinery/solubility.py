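"""Temperature-dependent TAL solubility in water and separation sub-models.

The solid-liquid equilibrium of a solid solute in a solvent below its
melting point is modeled with the classical relation

    ln(x * gamma(x)) = -(dHfus / R) * (1/T - 1/Tm)

where x is the solute mole fraction at saturation, dHfus the enthalpy of
fusion, Tm the melting temperature, and gamma the activity coefficient,
here the one-parameter van Laar form gamma = exp(A * (1 - x)**2).

The module also covers the separation physics built on that curve:
dissolution-temperature inversion, crystallization recovery against the
saturated mother liquor, and the pH-dependent ring-opening decarboxylation
loss of dissolved TAL to acetylacetone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

GAS_CONSTANT = 8.314462618  # J/mol/K
MOLAR_MASS_WATER = 18.015  # g/mol
MOLAR_MASS_TAL = 126.110  # g/mol  (C6H6O3)

# Density of liquid water, g/L, as a quadratic in Celsius temperature
# (fit to 0, 25 and 93 degC handbook values; <0.1% error over 0-100 degC).
WATER_DENSITY_COEFFS = (999.84, -4.62e-3, -4.279e-3)

__all__ = [
    "SolubilityRecord",
    "SoluteThermo",
    "DecarbModel",
    "water_density_g_per_L",
    "solubility_g_per_L",
    "saturation_mole_fraction",
    "fit_parameter",
    "dissolution_temperature",
    "decarboxylation_conversion",
    "crystallization_recovery",
    "calibrated_tal_thermo",
]


class SolubilityRecord(NamedTuple):
    """One (temperature, solubility) measurement."""

    temperature_C: float
    solubility_g_per_L: float


def water_density_g_per_L(T_C: float) -> float:
    a, b, c = WATER_DENSITY_COEFFS
    return a + b * T_C + c * T_C * T_C


@dataclass
class SoluteThermo:
    """Thermodynamic constants of the solute and the solvent conversion basis.

    ``solvent_density`` of None means "pure water at the local temperature"
    via the packaged density polynomial; a number pins a constant density.
    """

    melting_temperature_K: float
    fusion_enthalpy_J_per_mol: float
    molar_mass: float = MOLAR_MASS_TAL
    van_laar_A: float = 0.0
    solvent_density_g_per_L: float | None = None
    solvent_molar_mass: float = MOLAR_MASS_WATER

    def __post_init__(self) -> None:
        if self.melting_temperature_K <= 373.0:
            raise ValueError("melting_temperature_K must exceed 373 K")
        if self.fusion_enthalpy_J_per_mol <= 0:
            raise ValueError("fusion_enthalpy_J_per_mol must be positive")
        if self.solvent_density_g_per_L is not None and self.solvent_density_g_per_L <= 0:
            raise ValueError("solvent_density_g_per_L must be positive")

    def solvent_density(self, T_C: float) -> float:
        if self.solvent_density_g_per_L is not None:
            return self.solvent_density_g_per_L
        return water_density_g_per_L(T_C)


def _ideal_log_solubility(T_K: float, thermo: SoluteThermo) -> float:
    """RHS of the SLE relation: ln(x*gamma) at saturation."""
    return -(thermo.fusion_enthalpy_J_per_mol / GAS_CONSTANT) * (
        1.0 / T_K - 1.0 / thermo.melting_temperature_K
    )


def saturation_mole_fraction(T_C: float, thermo: SoluteThermo) -> float:
    """Solve ln(x) + A(1-x)^2 = ln(x*gamma)_ideal for x in (0, 1)."""
    T_K = T_C + 273.15
    if T_K >= thermo.melting_temperature_K:
        raise ValueError(
            f"temperature {T_C} degC is at or above the melting point; "
            "the solid-solute solubility model does not apply"
        )
    rhs = _ideal_log_solubility(T_K, thermo)
    A = thermo.van_laar_A

    def f(x: float) -> float:
        return np.log(x) + A * (1.0 - x) ** 2 - rhs

    lo, hi = 1e-300, 1.0 - 1e-12
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no saturation root bracketed in (0,1) for A={A}, T={T_C} degC"
        )
    return brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)


def mole_fraction_to_g_per_L(x: float, T_C: float, thermo: SoluteThermo) -> float:
    """Dilute-solution conversion: mass fraction times solvent density."""
    m_s = x * thermo.molar_mass
    m_w = (1.0 - x) * thermo.solvent_molar_mass
    w = m_s / (m_s + m_w)
    return w * thermo.solvent_density(T_C)


def g_per_L_to_mole_fraction(conc: float, T_C: float, thermo: SoluteThermo) -> float:
    w = conc / thermo.solvent_density(T_C)
    n_s = w / thermo.molar_mass
    n_w = (1.0 - w) / thermo.solvent_molar_mass
    return n_s / (n_s + n_w)


def solubility_g_per_L(T_C: float, thermo: SoluteThermo) -> float:
    """Equilibrium solubility in g solute per L solution at ``T_C``."""
    x = saturation_mole_fraction(T_C, thermo)
    return mole_fraction_to_g_per_L(x, T_C, thermo)


def fit_parameter(
    data: Sequence[SolubilityRecord],
    thermo: SoluteThermo,
    bounds: tuple[float, float] = (-10.0, 50.0),
) -> tuple[float, float]:
    """Least-squares fit of the van Laar parameter A to (T, g/L) data.

    Returns ``(A, r_squared)``. The objective is the sum of squared
    residuals in g/L (the reported/plotted quantity), minimized by bounded
    scalar search; deterministic given the data.
    """
    records = list(data)
    if len(records) < 2:
        raise ValueError("need at least 2 solubility records to fit")
    temps = np.array([r.temperature_C for r in records], dtype=float)
    obs = np.array([r.solubility_g_per_L for r in records], dtype=float)

    def sse(A: float) -> float:
        trial = SoluteThermo(
            thermo.melting_temperature_K,
            thermo.fusion_enthalpy_J_per_mol,
            thermo.molar_mass,
            A,
            thermo.solvent_density_g_per_L,
            thermo.solvent_molar_mass,
        )
        pred = np.array([solubility_g_per_L(t, trial) for t in temps])
        resid = pred - obs
        if not np.all(np.isfinite(resid)):
            raise ValueError("non-finite residuals during fit")
        return float(resid @ resid)

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-8})
    A_hat = float(res.x)
    ss_res = sse(A_hat)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return A_hat, r2


def dissolution_temperature(
    concentration: float,
    thermo: SoluteThermo,
    cap_C: float = 93.0,
    floor_C: float = 0.0,
) -> float:
    """Minimal temperature at which ``concentration`` g/L fully dissolves.

    Bisection on the (monotone) solubility curve to 0.01 degC; returns the
    search floor if the stream is already soluble there.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if solubility_g_per_L(floor_C, thermo) >= concentration:
        return floor_C
    s_cap = solubility_g_per_L(cap_C, thermo)
    if concentration > s_cap:
        raise ValueError(
            f"concentration {concentration:.2f} g/L exceeds solubility "
            f"{s_cap:.2f} g/L at the {cap_C} degC cap"
        )
    return brentq(
        lambda T: solubility_g_per_L(T, thermo) - concentration,
        floor_C, cap_C, xtol=0.005,
    )


@dataclass
class DecarbModel:
    """Piecewise-linear ring-opening decarboxylation loss vs maintained pH.

    Anchors default to the measured baseline (pH 2.10 -> 20.9 mol%) and the
    base-dosed mitigation point (pH 11.0 -> 4.8 mol%); conversions clamp to
    the nearest anchor outside the anchored range.
    """

    anchor_points: tuple[tuple[float, float], ...] = ((2.10, 0.209), (11.0, 0.048))

    def __post_init__(self) -> None:
        phs = [p for p, _ in self.anchor_points]
        convs = [c for _, c in self.anchor_points]
        if sorted(phs) != phs or len(set(phs)) != len(phs):
            raise ValueError("pH anchors must be strictly increasing")
        if any(not (0.0 <= c <= 1.0) for c in convs):
            raise ValueError("conversions must lie in [0, 1]")

    def conversion(self, pH: float) -> float:
        if not (0.0 <= pH <= 14.0):
            raise ValueError("pH must lie in [0, 14]")
        phs = np.array([p for p, _ in self.anchor_points])
        convs = np.array([c for _, c in self.anchor_points])
        return float(np.interp(pH, phs, convs))


def decarboxylation_conversion(pH: float, model: DecarbModel | None = None) -> float:
    """Mol fraction of dissolved TAL lost to acetylacetone at ``pH``."""
    return (model or DecarbModel()).conversion(pH)


def crystallization_recovery(C_in: float, T_cryst: float, thermo: SoluteThermo) -> float:
    """Mass fraction crystallized when cooling a C_in g/L solution to T_cryst.

    The mother liquor leaves saturated at S(T_cryst); undersaturated feeds
    yield zero.
    """
    if C_in < 0:
        raise ValueError("C_in must be non-negative")
    if C_in == 0:
        return 0.0
    s = solubility_g_per_L(T_cryst, thermo)
    return max(0.0, (C_in - s) / C_in)


def calibrated_tal_thermo(
    anchor_low: tuple[float, float] = (0.0, 3.52),
    anchor_high: tuple[float, float] = (93.0, 130.65),
    melting_temperature_K: float = 462.15,
) -> SoluteThermo:
    """TAL thermodynamics calibrated to the two observed solubility extremes.

    The melting temperature is pinned at the literature value (~189 degC);
    the fusion enthalpy and van Laar parameter are then uniquely determined
    by requiring the model to pass through the minimum (3.52 g/L at 0 degC)
    and maximum (130.65 g/L at 93 degC) observed solubilities. Eliminating
    dHfus between the two anchor equations leaves a 1-D root problem in A.
    """
    probe = SoluteThermo(melting_temperature_K, 1.0)  # conversion basis only
    (t_lo, s_lo), (t_hi, s_hi) = anchor_low, anchor_high
    x_lo = g_per_L_to_mole_fraction(s_lo, t_lo, probe)
    x_hi = g_per_L_to_mole_fraction(s_hi, t_hi, probe)

    def dh_from(A: float, x: float, t_C: float) -> float:
        T_K = t_C + 273.15
        lhs = np.log(x) + A * (1.0 - x) ** 2
        return -lhs * GAS_CONSTANT / (1.0 / T_K - 1.0 / melting_temperature_K)

    A = brentq(
        lambda a: dh_from(a, x_lo, t_lo) - dh_from(a, x_hi, t_hi),
        -5.0, 20.0, xtol=1e-12,
    )
    dh = dh_from(A, x_lo, t_lo)
    return SoluteThermo(melting_temperature_K, dh, van_laar_A=A)
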