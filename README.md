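# glacialch4

Methane budgets for land-terminating glacial runoff.

Glacial melt rivers and paraglacial lakes can be strongly supersaturated
in methane flushed from anoxic subglacial environments, but microbial
methane oxidation (methanotrophy) in oxygenated paraglacial sediments can
remove a large fraction of that load before it reaches the atmosphere.
`glacialch4` implements the full calculation chain needed to quantify
this budget from field measurements:

1. **Headspace inversion** — recover the dissolved CH4 concentration of
   a water sample from a post-equilibration helium-headspace GC reading,
   by mass balance over the gas (ideal) and aqueous (Henry's law) phases.
2. **Incubation rates** — net methane production/oxidation from
   sediment–water bottle assays, `(mean final − mean initial) / Δt`,
   expressed per litre of water, per m² of sediment surface, and per
   gram of sediment.
3. **Gas transfer** — `k600` from river hydraulics via the stream energy
   dissipation rate `eD = g·S·v` and `ln k600 = 6.43 + 1.18 ln eD`, or
   from lake wind speed; Schmidt-number correction to the CH4 transfer
   velocity `kx` through `k600/kx = (600/Scx)^n` with `n = −1/2`.
4. **Diffusive flux** — the thin-boundary-layer model
   `F = kx (Cw − Ceq)`.
5. **Reach attenuation** — residence time `τ = L / (Q / (w·d))` and
   zero-order in-transit oxidation, `removed = min(rate·τ, C0)`.
6. **Upscaling** — per-area glacier fluxes (Mg km⁻² yr⁻¹) extrapolated
   to global glacier coverage (Tg yr⁻¹).

A synthetic-data module generates headspace and incubation measurement
tables with known ground truth and configurable Gaussian noise, so every
stage is testable offline and parameter recovery is demonstrable.

## Worked example

The reference scenario (an Icelandic paraglacial river at 1 °C, channel
slope 0.01, water velocity 4 m s⁻¹):

```console
$ glacialch4 k600 --model river
k600: 205.4 m/d
Sc(CH4, 1.0 degC): 1792.5
kx: 118.8 m/d (n = -0.5)
```

Energy dissipation 9.8 × 0.01 × 4 = 0.392 W kg⁻¹ gives a very high
transfer velocity (205.4 m d⁻¹ at Schmidt 600); correcting to CH4 in
near-freezing water (Sc ≈ 1792) lowers it to 118.8 m d⁻¹. With the
measured excess concentration of 0.53 µM this yields a diffusive
emission of ~63 mmol CH4 m⁻² d⁻¹.

In-transit oxidation over a 4 km reach at a measured net oxidation rate
of 2.97 µmol L⁻¹ d⁻¹:

```console
$ glacialch4 attenuate --c0 0.53 --rate 2.97 --discharge 50 --discharge 10
 discharge_m3_s  residence_time_min  removed_um  fraction_removed_pct  fraction_removed_rounded_pct
           50.0           26.666667       0.055             10.377358                     11.320755
           10.0          133.333333       0.275             51.886792                     52.830189
```

Water transits the reach in 27 min at summer discharge (50 m³ s⁻¹) and
133 min at winter discharge (10 m³ s⁻¹); oxidation removes 11–53 % of
the methane load in transit (the `rounded` column follows the common
report convention of rounding the removed mass to 2 d.p. before the
ratio; the exact fractions are 10.4 % and 51.9 %).

Glacier upscaling from published source fluxes:

```console
$ glacialch4 upscale
          name  annual_flux_mg_yr  area_km2  per_area_flux_mg_km2_yr  global_flux_tg_yr
      Leverett                6.3      20.0                 0.315000           0.214200
      Svalbard             2310.0    6268.0                 0.368539           0.250606
Solheimajokull             2460.0       9.0               273.333333         185.866667
```

The three source glaciers span three orders of magnitude in per-area
flux, hence the 0.21–186 Tg yr⁻¹ spread in the naive global
extrapolation over 680,000 km² of glacier coverage — the motivation for
measuring oxidation in receiving waters at all.

`glacialch4 reproduce` runs the whole chain and prints a report
comparing every computed quantity with its published reference value;
`glacialch4 simulate --seed N --out dir/` writes a synthetic dataset
with a truth manifest, which `glacialch4 headspace` and
`glacialch4 rates` can then analyse.

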