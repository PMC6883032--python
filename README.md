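# tidalcarbon

Blue-carbon accounting for tidal wetlands: from sediment-core compilations
to national carbon-sequestration budgets and end-of-century projections.

Tidal marshes and mangroves bury atmospheric carbon in their soils as they
accrete vertically, and — unlike upland soils — do not saturate, because
relative sea-level rise (RSLR) keeps creating accommodation space.
`tidalcarbon` implements the full analysis chain a national assessment of
this sink needs, for coastal biogeochemists and carbon accountants working
from literature compilations and wetland inventories:

1. **Core harmonization** (`tidalcarbon.cores`) — loss-on-ignition (LOI) to
   organic-carbon content (divisor 1.724 for mangrove / tidal-freshwater
   soils; the salt-marsh quadratic `TOC% = 0.04·LOI% + 0.0025·LOI%²` for
   brackish / salt-marsh soils), bulk density from the organic/mineral
   self-packing mixing model `BD = 1/(LOI/k₁ + (1−LOI)/k₂)` with
   k₁ = 0.085 and k₂ = 1.99 g cm⁻³, carbon accumulation rate
   `CAR = C density × SAR × 1000` (g C m⁻² yr⁻¹), top-30-cm profile
   averaging, salinity-based vegetation classes (0–0.5 / 0.5–18 / >18 ‰),
   and exclusion of ¹⁴C-dated records.
2. **Sea-level trends** (`tidalcarbon.rslr`) — OLS trends of annual
   mean-sea-level over the most recent 60 years, a linear bridge mapping
   30-year records onto the 60-year basis, and nearest-gauge assignment of
   RSLR to sites.
3. **Upscaling** (`tidalcarbon.upscale`) — per-polygon CAR as the mean of
   compiled sites within a 100-km radius (regional mean and CI as fallback
   when fewer than two sites are in range), flux = CAR × area × 10⁻⁶
   Tg yr⁻¹, and confidence intervals of sums propagated in quadrature:
   δ_sum = √(Σ δᵢ²), 95% CI = 1.96 × δ_sum. Uniform (one national mean)
   and stratified (group mean × group area) estimators are included for
   comparison.
4. **Statistics** (`tidalcarbon.stats`) — one-way ANOVA with Tukey-HSD
   compact letter displays, Pearson and first-order partial correlations,
   and the predictive model CAR ~ RSLR with plain, source-clustered, or
   random-intercept errors.
5. **Projection** (`tidalcarbon.project`) — decadal CAR to 2100 via
   `CAR_t = max(0, CAR₀ + slope × (min(RSLR_t, crit) − min(RSLR₀, crit)))`
   with a critical RSLR of 10 mm yr⁻¹ (accretion stops keeping pace beyond
   it), combined with scenario area-change trajectories and a Monte-Carlo
   95% band.

A calibrated synthetic-data generator (`tidalcarbon.synthetic`) emulates
the compilation's regional and vegetation structure — including a CAR–RSLR
correlation of 0.40 — so the whole pipeline runs and is tested without any
external downloads.

## Worked example

```sh
tidalcarbon simulate --seed 1 --out ex
tidalcarbon upscale --sites ex/sites.csv --inventory ex/inventory.csv --radius-km 100 --out ex/up
tidalcarbon stats --sites ex/sites.csv --out ex/st
tidalcarbon project --scenario ex/scenarios.csv --model ex/st/model.json --draws 5000 --seed 1 --out ex/proj.csv
```

prints

```
national flux 4.860 ± 0.092 Tg C yr⁻¹ over 1400 polygons
CAR~RSLR slope 21.18 ± 3.02 (fit_mode=cluster_robust, n=350)
RCP2.6/thr300: 2100 flux 9.37 (95% band 8.54–10.21) Tg C yr⁻¹
RCP4.5/thr300: 2100 flux 10.50 (95% band 9.41–11.61) Tg C yr⁻¹
RCP8.5/thr300: 2100 flux 11.08 (95% band 9.85–12.34) Tg C yr⁻¹
```

Reading the numbers: the interpolated inventory total (4.86 Tg C yr⁻¹ with
its E1/E2 95% half-width) lands between the uniform estimate
(161.8 g C m⁻² yr⁻¹ × 25,892 km² = 4.19 Tg yr⁻¹) and the regional-sum
estimate, as expected when high-CAR regions hold much of the area; each
additional mm yr⁻¹ of RSLR raises CAR by ~21 g C m⁻² yr⁻¹; and under an
unrestricted accommodation-space scenario the 2100 sequestration roughly
doubles, with the ordering RCP8.5 ≥ RCP4.5 ≥ RCP2.6 per decade.
`tidalcarbon run --config config.yaml` chains all stages and writes a
`manifest.json` whose per-stage record counts reconcile.

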