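# Methods

This note documents the models, parameter choices, numerical methods and
limitations behind `tal_biorefinery`.

## Stoichiometric basis

Every yield in the package derives from an element-balanced reaction with
explicit O2/H2O closure, checked by exact integer arithmetic:

- glucose route: 3 C6H12O6 + 6 O2 → 2 C6H6O3 + 6 CO2 + 12 H2O
  (0.4667 g TAL per g glucose),
- acetate route: 9 C2H4O2 + 6 O2 → 2 C6H6O3 + 6 CO2 + 12 H2O
  (0.4667 g TAL per g acetic acid — identical to the glucose route, the
  unique integer stoichiometry with that property),
- upgrading: C6H6O3 + 2 H2 → C6H8O2 + H2O (0.889 g sorbic acid/g TAL),
- ring-opening decarboxylation: C6H6O3 + H2O → C5H8O2 (acetylacetone) + CO2,
- end-of-life oxidation: C6H6O3 + 6 O2 → 6 CO2 + 3 H2O (2.09 kg CO2/kg).

Atomic masses are IUPAC 2021 package constants, so molar masses carry no
external lookups. Sucrose enters fermentation as glucose equivalents
through its hydrolysis stoichiometry (1.0527 g glucose/g sucrose); the
water of hydrolysis is tracked in the balances.

## Solubility model

Solid-solute equilibrium: ln(x·γ) = −(ΔH_fus/R)(1/T − 1/T_m) with the
one-parameter van Laar activity coefficient γ = exp(A(1−x)²). The
saturation mole fraction is found by Brent root search on (0, 1) to
1e−14; mole fraction converts to g·L⁻¹ as mass fraction times solvent
density, with water density from a packaged quadratic in temperature
(≤0.1% error over 0–100 °C). This dilute-solution conversion is a
modeling convention; it is applied consistently in both directions so
calibration and inversion are self-consistent.

The melting temperature of TAL is pinned at 462.15 K (literature melting
point ≈189 °C). The fusion enthalpy and van Laar parameter are **jointly
calibrated** so the curve passes exactly through the observed extremes
(3.52 g/L at 0 °C, 130.65 g/L at 93 °C): eliminating ΔH_fus between the
two anchor equations leaves a one-dimensional root problem in A. The
result, ΔH_fus ≈ 33.1 kJ/mol and A ≈ 1.63, is physically plausible for a
small hydrogen-bonding organic solid. Both values are exposed in the
configuration and flagged as calibrated defaults; any user dataset can
re-fit A by bounded least squares in g/L (the measured/plotted quantity),
with R² reported against the data mean.

Fitting tolerances: bounded scalar minimization with xatol = 1e−8 on A;
dissolution-temperature inversion by Brent bisection to 0.01 °C.

Decarboxylation is a single per-pass mol-fraction loss applied at the
dissolution step, interpolated linearly in maintained pH between the
anchors (2.10, 20.9%) and (11.0, 4.8%) and clamped outside. A kinetic
temperature-time model would be more faithful to the underlying
chemistry but scenario-level conversions are what the analysis consumes.

## Flowsheet

Flows are kg/h at steady state; broth volume uses the water-mass
convention (1 L per kg water), consistent with the dilute-solution
solubility basis. The juice sugar target is computed analytically so the
fermented broth lands exactly on the design titer — the model is linear
in scale, so this target is independent of plant size, and doubling the
feed doubles every flow exactly.

Feedstock composition (wet basis: water 0.70, sucrose 0.135, glucose
0.015, fiber 0.135, ash 0.015) and the juicing extraction efficiency
(0.92) are calibrated defaults. The sodium acetate co-feed ratio
(≈0.20 g acetic-acid-eq per g glucose-eq) is solved at configuration
build time so the baseline lands exactly on the 13,385 t TAL/y design
capacity from 620,540 wet t cane/y over 180 operating days.

Fermentation products: TAL at 40.5% of the theoretical 0.467 g/g on
total substrate; citric acid at 0.094 g per g glucose-equivalent
(applied to glucose equivalents from all sugars — the source statement
is ambiguous between glucose only and all sugars); cell mass
(C5H9NO2) at 0.10 g/g substrate, a calibrated default. CO2, O2 and water
close C/H/O exactly; cell nitrogen is drawn as ammonia from diammonium
phosphate, whose non-ammonia remainder reports to the broth as phosphate
salts (the split (NH4)2HPO4 = 2 NH3 + H3PO4 is mass-exact). Batch time is
titer/productivity (299.2 h at baseline); vessel count is
ceil(volume/3,000 m³).

Separation recovery factors exactly as
(1 − decarboxylation) × crystallized fraction × crystal retention;
at baseline 0.791 × 0.869 × 0.95 = 0.658. NaOH demand for pH-maintained
separation is a stoichiometric floor: a linear ramp toward full
neutralization of citric + phosphoric + TAL acidity at pH 11.

Facilities: bagasse (fiber LHV 17.5 MJ/kg, sugars 15.6, minus the
evaporation penalty of its moisture) and digester biogas (0.30 m³ CH4
per kg COD, COD from theoretical oxygen demand of each organic species)
fire a boiler (80%); steam first covers the process heating duty and the
surplus drives a turbogenerator (28%) whose output, net of parasitic
load (25 kWh/t cane) and chilled-water duty (COP 3.5), is exported.

## TEA

Power-law costing (cost = anchor·(size/anchor_size)^0.6 per unit class)
replaces detailed equipment-design algorithms; this preserves the
response surface (deltas, rankings, maps) that the analysis interrogates
while keeping the model desk-scale. A single global anchor-cost
calibration factor (0.5877) was fitted **once** so the baseline
configuration prices TAL at the design-basis MPSP of $4.60/kg, and is
never adjusted elsewhere; all other results (Monte Carlo envelopes,
scenario deltas, maps) are model outputs around that anchor.

Cash flow: 3-year construction (8/60/32% of fixed capital), working
capital 5% committed at startup and recovered in the final year,
straight-line depreciation over 10 years, 21% income tax on positive
taxable income, 30 operating years, 10% discount rate. MPSP is the Brent
root of NPV(price) with xtol 1e−8, which leaves |NPV| well under $1,000
on a ~$10⁸ scale. All prices are 2019 USD. The natural-gas price is
0.218 $/kg (~$4.1/MMBtu): quoted figures of tens of dollars per kg are not
physically plausible as mass prices and were treated as unit anomalies.

## LCA

Functional unit 1 kg TAL. Gross CI = Σ inventory × factor + end-of-life
oxidation (2.09 kg CO2/kg, taken from the stoichiometry module so the
two stay consistent by construction); offset = −export × grid factor;
net = gross + offset, exact to 1e−12. Biogenic CO2 (fermentation vent,
biomass-fuel combustion) is carbon-neutral; the feedstock factor
excludes credit for fixed carbon and includes direct (not indirect)
land-use change. Characterization factors are documented placeholders
standing in for GREET-2022-sourced values (e.g. grid 0.48 kg CO2-eq and
6.1 MJ fossil per kWh); grid-factor uncertainty is excluded from Monte
Carlo by default. With the packaged factors the baseline nets
6.92 kg CO2-eq/kg and +85 MJ/kg: this flowsheet exports ≈6.7 kWh/kg of
electricity, so its displacement credits are smaller than a design with
a larger surplus-power train would earn, and net FEC stays positive.

## Uncertainty machinery

LHS: per parameter, one uniform draw inside each of n equal-probability
strata, independently permuted (numpy PCG64, explicit seed; default
20250501). Distribution inverses: closed-form uniform, scipy triangular.
The stratification property is exact for every n and is tested as such.

Spearman screening uses midrank ties and the t-approximation for
p-values (exact permutation would be prohibitive at n = 6000); the
significance rule is |ρ| ≥ 0.10 **and** p < 0.05. At n = 6000 the ρ
threshold dominates and the null false-flag probability is ~1e−14, i.e.
numerically zero — verified by simulation. Constant outputs have
undefined ρ and are reported as 0, unflagged, with a note.

Monte Carlo records failed evaluations as NaN rows (never dropped
silently) and flags the run above 1% failures. Percentiles use the
linear-interpolation definition. Default production sample count is
6000 with a 300-sample test profile; the packaged parameter table holds
30 distributions (triangular, baseline-as-mode, for process parameters;
uniform for prices) bound to real configuration paths.

Grid maps evaluate full factorials with all other parameters at
baseline. Feasibility: the required substrate concentration
titer/(0.467 × yield fraction) must not exceed a configurable maximum
fermentable-sugar concentration (600 g/L default), which reproduces the
characteristic infeasible low-yield/high-titer wedge. Production
capacity maps scale the annual feed through a capacity factor, keeping
hourly concentrations unchanged (the model is flow-linear).

## What the synthetic fixtures do and do not emulate

The fixtures reproduce the *structure* of realistic inputs: a 12-point
(T, solubility) dataset spanning 0–93 °C with ~3% multiplicative noise,
a 30-parameter uncertainty table, and a baseline configuration carrying
every design-basis value. They do not emulate raw measurement artifacts
(replicate scatter structure, instrument drift) or the supplementary
cost/inventory tables of a full process-simulation platform. Passing
tests therefore demonstrate the correctness and internal consistency of
the analysis machinery on realistically structured inputs — not
agreement with any specific laboratory dataset.

## Known limitations

- Equipment costs are power-law anchors, not designed equipment; absolute
  capital figures are indicative only.
- The dilute-solution volume convention overstates concentrations by a
  few percent near the solubility maximum (~13 mass% TAL).
- Decarboxylation ignores time-temperature kinetics.
- Heat integration is a simple steam cascade; no exchanger-network
  synthesis, multi-effect staging beyond an effect factor, or detailed
  wastewater train design.
- LCA covers GWP100 and FEC only, with placeholder characterization
  factors; electricity export in this flowsheet is modest, so net FEC is
  positive where a design with larger surplus power would show net
  displacement.
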