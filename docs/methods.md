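# Methods

This note documents the models implemented in `glacialch4`, the
coefficient sets and defaults chosen where the underlying field
procedure left them open, and the package's known limitations.

## Headspace equilibration and inversion

A water sample is sealed in a vial (nominally 70 mL), part of the water
is replaced by an ultra-pure helium headspace (nominally 20 mL, leaving
50 mL of water), and the phases equilibrate for ~24 h before the
headspace is analysed by GC. Because the headspace is initially
CH4-free, all methane found afterwards — in the gas phase and still
dissolved — originated in the water, so the original concentration is

    C0 = [ p·Vh/(R·T)  +  kH(T)·p·Vw ] / Vw

with `p` the CH4 partial pressure implied by the measured mole fraction,
`Vh`/`Vw` the headspace/water volumes, and `kH` the Henry coefficient at
the equilibration temperature. Assumptions: ideal-gas headspace (no
fugacity correction at ambient pressure), full equilibration, and a
negligible volume displacement from the ZnCl2 preservative drops (≤2 mL
against 70 mL). The forward model (`equilibrate_headspace`) is the exact
algebraic inverse, which the round-trip property tests exploit.

The equilibration temperature is rarely reported with field data; the
default is 20 °C (laboratory conditions) and it must travel with each
vial record — the inversion is sensitive to it through both the gas
density and the solubility.

## Solubility and Schmidt numbers

* **Solubility**: the CH4 Bunsen-coefficient fit of Wiesenburg &
  Guinasso (1979), evaluated at salinity 0 and divided by the STP molar
  volume (22.414 L mol⁻¹) to give mol L⁻¹ atm⁻¹. Applied range −2 to
  30 °C (the fit's dilute-water range); out-of-range temperatures raise.
* **Equilibrium concentration**: `Ceq = kH(T) · x_CH4 · P` with a
  default atmospheric mixing ratio of 1870 ppb and 1 atm, both
  configurable. At 1 °C this gives Ceq ≈ 0.005 µM — two orders of
  magnitude below the ~0.5 µM observed in supersaturated glacial rivers,
  so excess concentrations are insensitive to the exact mixing ratio.
* **Schmidt number**: the fresh-water CH4 quartic of Wanninkhof (2014).
  The polynomial's formal minimum sits near 37 °C, so the applied range
  is capped at 35 °C to keep the physically expected monotone decrease;
  glacial applications live at the cold end anyway.

## Gas transfer velocities

* **River**: energy dissipation `eD = g·S·v` (default g = 9.8 m s⁻²,
  S = 0.01, v = 4 m s⁻¹, giving eD = 0.392 W kg⁻¹) fed into the
  high-energy-dissipation relationship of Ulseth et al. (2019),
  `ln k600 = 6.43 + 1.18 ln eD` → 205.4 m d⁻¹. g = 9.8 rather than 9.81
  is the default because it reproduces the reference value exactly
  (9.81 gives 205.6); it is configurable. The low-energy branch of the
  Ulseth relationship is out of scope.
* **Lake**: a piecewise-linear wind relationship after the steady-wind
  bilinear fit of Crusius & Wanninkhof (2003), anchored to return
  0.27 m d⁻¹ at u10 = 3.7 m s⁻¹. **Caveat**: the original fit is
  expressed in cm h⁻¹; converting those coefficients literally to
  m d⁻¹ yields ≈0.64 m d⁻¹ at 3.7 m s⁻¹, a factor ~2.4 above the anchor
  this package is required to reproduce. The adopted coefficients
  (0.072·u10 below the 3.7 m s⁻¹ break; 0.433·u10 − 1.33 above) are the
  original slopes rescaled by 1/10, which preserves the anchor and the
  bilinear shape. The constants table records this provenance; anyone
  needing the strict Crusius & Wanninkhof values should scale the lake
  k600 by 2.4.
* **Schmidt scaling**: `kx = k600 / (600/Scx)^n` with `n = −1/2` for
  both the turbulent river surface and the wavy lake surface (exposed as
  a parameter, valid range −1 to −1/3). At Sc = 600 the scaling is the
  identity for any n.

## Diffusive flux and its unit

`F = kx (Cw − Ceq)`. With kx in m d⁻¹ and the excess in µM — which is
numerically identical to mmol m⁻³ — the dimensionally consistent flux
unit is **mmol m⁻² d⁻¹** (river: 118.8 × 0.53 ≈ 63 mmol m⁻² d⁻¹).
Published glacial-river values with these same digits are frequently
labelled µmol m⁻² d⁻¹, a 10³ inconsistency; the package computes
dimensionally and renders both scales, and `oxidation_vs_emission`
refuses to form a sink/source ratio unless the caller names the unit of
each operand explicitly.

## Incubation rates

Net rate = (mean final − mean initial)/Δt, per day; negative = net
oxidation. Replicates are aggregated by the mean with no outlier
rejection. Re-expressions share one water volume: 70 mL per bottle
(5 mL sediment slurry + overlying water; the areal reference value
157.5 µmol m⁻² d⁻¹ = 2.97 × 0.070 L / 1320 mm² reproduces only with
0.070 L, so that is the default even though slurry displacement suggests
~65 mL of water). The sediment surface is the bottle's inner circle
(41 mm → 1320 mm² at 4 s.f.); mass-specific rates use the slurry volume
(5 mL) times bulk density (default 0.96 g mL⁻¹ of the reported
0.70–0.96 range, the conservative end for the rate magnitude).

A lake rate of +0.12 µmol L⁻¹ d⁻¹ has the mass equivalent
0.12 × 16.04 = 1.9 µg L⁻¹ d⁻¹. Reference tables sometimes relabel this
per-litre magnitude as an areal rate (1.9 µg m⁻² d⁻¹); the geometric
conversion (× 0.070 L / 1.32×10⁻³ m²) gives a different number
(~102 µg m⁻² d⁻¹). The report computes the mass equivalent and flags
the relabelling in its note rather than choosing silently.

## Reach attenuation

Residence time from hydraulic continuity: `v = Q/(w·d)`, `τ = L/v`
(4 km × 20 m × 1 m defaults; 50 and 10 m³ s⁻¹ summer/winter
discharges → 26.7 and 133.3 min). Removal is zero-order — a constant
volumetric oxidation rate over the transit, clamped at the available
methane — because the measured rate is a single net value with no
concentration dependence attached; a first-order treatment would need a
rate constant the bottle assays cannot supply. Starting from 0.53 µM at
2.97 µmol L⁻¹ d⁻¹ the exact reductions are 10.4 % and 51.9 %; the
report additionally renders the chain in which the removed mass is
rounded half-up to 2 d.p. before the ratio (0.055 → 0.06, 0.275 → 0.28,
giving 11 % and 53 %), labelled as such, because that is how the
reference figures were printed. No re-aeration, longitudinal dispersion
or along-reach methane inputs are modelled.

## Upscaling

Per-area flux = annual flux / glacier area; global flux = per-area ×
680,000 km² of global glacier coverage (configurable), Mg → Tg. The
three reference sources are Leverett (6.3 Mg yr⁻¹ / 20 km²), the
Svalbard archipelago glaciers (2310 Mg yr⁻¹ / 6268 km²) and
Sólheimajökull (2460 Mg yr⁻¹ = 41 Mg d⁻¹ × 60 melt days / 9 km²).
Two rounding notes: Svalbard's per-area flux computes to 0.3685
(half-up 0.37) where the reference table shows 0.36, and the
Sólheimajökull global value computes to 185.9 Tg yr⁻¹ where 185 was
printed; the report carries both computed values with the reference
figure in a comparison column. No uncertainty propagation is attempted.

## Synthetic data

The generator emulates the deposited field-data structure: duplicate
headspace vials per site and triplicate initial/final incubation vials
per site. Ground truth defaults mirror the reference scenario — river
0.536 µM dissolved CH4 with net oxidation −2.97 µmol L⁻¹ d⁻¹ over 21 h,
lake 0.23 µM with net production +0.12 µmol L⁻¹ d⁻¹ over 22 h, 1 °C
water. The sediment-slurry bottles start from their own initial
concentration (river 3.0 µM, lake 1.0 µM) well above the surface-water
value, as sediment-associated methane dominates the bottle inventory;
without this the river's strong oxidation would drive final
concentrations negative.

Noise is additive Gaussian on concentration (default sd 0.02 µM, ~4 %
of the river value — a plausible GC replicate precision), applied before
the forward headspace partitioning, with final concentrations truncated
at zero and flagged. A single seeded `numpy` generator threads through
all draws; identical scenarios produce byte-identical files. The
generator does **not** emulate GC calibration drift, between-vial
geometry variation, spatial/temporal autocorrelation, or re-aeration
during incubation — passing recovery tests therefore demonstrate that
the estimator chain is correct and unbiased under the stated noise
model, not that field data of this shape are free of systematic error.

## Problem sizes and numerics

The full reproduction chain is closed-form and runs in well under a
second. Stochastic recovery checks use 200 simulated triplicate assays
(estimator bias within 2 standard errors) and fixed seeds; hypothesis
property tests run derandomised. Report pass/fail tolerances are half a
unit of the reference value's last printed digit, widened (with an
explanatory note) only for the documented rounding-chain quantities
(the 11 %/53 % reductions, the 0.06/0.28 µM removed masses, Svalbard's
0.36, Sólheimajökull's 185).
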