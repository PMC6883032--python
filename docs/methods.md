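# Methods

This note records the models implemented by `tidalcarbon`, the defaults
and why they hold, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Core harmonization

Literature compilations of dated sediment cores rarely report carbon
density directly, so site records are reconstructed from whichever of LOI,
bulk density (BD), and organic-C content a study provides.

* **LOI → organic C.** Mangrove and tidal-freshwater soils use the
  organic-matter divisor `TOC = LOI / 1.724` (the classical van-Bemmelen
  factor). Brackish and salt-marsh soils use a marsh-specific quadratic in
  LOI *percent*, `TOC% = 0.04·LOI% + 0.0025·LOI%²`. The linear coefficient
  is exposed as `ConversionParams.quad_a` because the commonly cited
  original calibration uses 0.40 where some compilations print 0.04; the
  default keeps the printed 0.04. Note the two rules deliberately take LOI
  in different units (fraction vs percent); conversion happens inside the
  function so callers always pass mass fractions.
* **LOI → BD.** The self-packing mixing model treats bulk volume as the
  sum of the self-packing volumes of the organic and mineral components:
  `BD = 1/(LOI/k₁ + (1−LOI)/k₂)`, with k₁ = 0.085 g cm⁻³ (pure organic)
  and k₂ = 1.99 g cm⁻³ (pure mineral). BD is strictly decreasing in LOI
  and bounded by the end-member densities.
* **CAR.** `CAR = C density × SAR × 1000`: one mm of accretion adds
  1000 cm³ of new sediment per m². Layered profiles are averaged with
  thickness weights over the top 30 cm — the horizon recording roughly the
  last century of accumulation, matching the decadal ²¹⁰Pb/¹³⁷Cs dating
  scale. ¹⁴C-dated records are excluded from CAR statistics because
  centennial-scale rates read systematically low against decadal ones.
* **Vegetation classes.** Salinity below 0.5 ‰ is tidal freshwater,
  the closed interval [0.5, 18] ‰ brackish ("0.5 to 18" reads inclusive;
  both boundaries go to brackish), above 18 ‰ salt marsh; a mangrove flag
  overrides salinity.
* Records lacking both LOI and a (BD, C content) pair cannot be placed on
  the common footing and are dropped with a logged reason. Multi-core
  sites are reduced by averaging cores per site. Negative user-supplied
  SAR is rejected rather than clamped — accretion rates in compilations
  are positive, and silently clamping would hide data errors.

## Sea-level trends

RSLR is the OLS slope of annual mean sea level on year over the most
recent 60 calendar years, long enough to damp the decadal variability that
dominates short tide-gauge trends. A window is usable when at least 80% of
its annual values are present (48 of 60; 24 of 30) — gap tolerance has to
be pinned somewhere, and 80% keeps single-decade gaps from discarding a
gauge while refusing seriously fragmentary records. Gauges with only the
short window are mapped to the 60-yr basis through an OLS bridge
`trend60 ~ a + b·trend30` fitted on gauges supporting both windows (≥ 3
training pairs required; the intercept is kept because short-window trends
are biased by decadal phase). Bridged slopes carry
`se = √((b·se₃₀)² + s_resid²)`, inflating uncertainty by the bridge's
residual scatter; a gauge with a full 60-yr trend is never bridged.
Sites take the trend of the nearest gauge by great-circle distance on a
6371-km sphere (sub-km geodesy is irrelevant at 100-km scales), ties
breaking to the lexicographically lower gauge id.

## Upscaling and error propagation

Each inventory polygon takes the unweighted mean CAR of the compiled sites
within 100 km of its centroid (boundary inclusive), with SE = sample
SD/√n. No inverse-distance weighting is applied — the neighborhood rule is
"sites within the radius", nothing finer. Polygons with zero or one site
in range (exactly 2 neighbors still interpolate) fall back to their
region's mean CAR and the regional *mean's* SE — the fallback inherits the
uncertainty of the regional average, not the site-to-site SD, because the
regional mean is what is being imputed. Fluxes are CAR × area × 10⁻⁶
(Tg yr⁻¹); sums propagate SEs in quadrature (δ_sum = √Σδᵢ², 95% CI =
1.96·δ_sum) under independent polygon errors. That independence is
knowingly optimistic — neighboring polygons share neighbor sites — so
`aggregate(..., cluster_col=...)` offers a cluster-aware variant that adds
SEs linearly within groups of polygons sharing an identical neighbor set
and in quadrature across groups; it is off by default to keep the standard
propagation the reference behavior. Totals are kept at full precision
internally and rounded only at the reporting layer.

## Statistics

Group comparisons use classical one-way ANOVA plus Tukey HSD (studentized
range, with the Tukey–Kramer harmonic-mean adjustment for unequal group
sizes) and a compact letter display built by insert-and-absorb: two groups
share a letter iff not significantly different. The CAR–SAR and CAR–C
density entries of the correlation table are first-order partial
correlations controlling for the respective other driver — SAR and C
density jointly compose CAR, so raw pairwise correlations double-count
their shared variance. No multiplicity correction is applied across the
correlation table (noted in the report header).

The predictive model is CAR ~ RSLR. The default fit is OLS coefficients
with standard errors clustered on the literature source: sites extracted
from one publication share methods, location, and often cores, and
clustering honors that dependence without extra structure. A
random-intercept mixed model (REML, via statsmodels MixedLM) is available
as `fit_mode="random_intercept"` for users who prefer explicit
source-level intercepts; plain OLS is kept for transparency. An
exhaustive model search over region/vegetation/climate covariates is
deliberately not performed — the model form is an input here, not a
discovery.

## Projection

`CAR_t = max(0, CAR₀ + slope × (min(RSLR_t, crit) − min(RSLR₀, crit)))`,
with crit = 10 mm yr⁻¹ by default (12 mm yr⁻¹, the southeast-US marsh
limit, is a supported alternative). Applying the cap to both the current
and future rate means a segment already beyond the critical rate gains
nothing further — the cap is a statement about accretion, not about the
calendar. CAR is floored at zero after perturbation. National flux per
decade is Σ segments of CAR_t × baseline area × area-fraction(t) × 10⁻⁶.

The 95% band comes from Monte-Carlo draws (default 10⁴) of baseline CAR ~
N(CAR₀, SE²) per segment and slope ~ N(slope, SE²); decadal RSLR paths and
area fractions are treated as fixed inputs, so the band reflects only
baseline-CAR and slope uncertainty and understates the full predictive
spread. The seed and draw count are recorded in the result's provenance.

## Synthetic generator

The generator reproduces the statistical structure the analysis assumes:
seven coastal watershed regions with their compiled CAR / SAR / RSLR means
and SEs and wetland areas, four vegetation classes with their C densities
and area shares, sites grouped into literature sources of ~5–10, gauges
with known ground-truth trends (25% short records), log-normally sized
polygons clustered near the site clusters, and scenario trajectories whose
2100 RSLR increment scales with emissions severity (3 / 5 / 9 mm yr⁻¹ for
the three pathways) and whose area fractions run from 1 at 2020 to
0.78 / 0.92 / 1.20 / 1.45 under accommodation thresholds of 5 / 20 / 150 /
300 people km⁻² — endpoints chosen to mirror the reported behavior of
coupled wetland-migration models: up to ~25% loss when almost no
accommodation space exists, roughly flux doubling with under +50% area
when unrestricted.

CAR is generated as c_density × SAR × 1000 plus a stored noise term, so
the identity is testable record by record. The noise does three jobs, in
order: (1) rescales each region's within-region dispersion to the
compilation-implied site SD (SE × √n) — the raw density×accretion product
disperses far more than compiled CAR does; (2) centers each region exactly
on its configured mean; (3) calibrates the all-site CAR–RSLR correlation
to the 0.40 target by Brent's method, adding either region-mean-zero
independent noise (scaled proportionally to the regional mean, so low-CAR
regions are not pushed against the positivity floor) or a within-region
RSLR-aligned tilt, whichever direction is needed. A final positivity floor
at 1 g C m⁻² yr⁻¹ re-centers regional means iteratively; the realized
correlation ends within a few hundredths of the target. With
`calibrate_car=False` and zero SEs, CAR is exactly the product of the
configured means — the degenerate configuration the unit tests exercise.

What the generator does **not** emulate: real polygon geometry and tidal
datums, spatially correlated residual fields beyond cluster placement,
serial correlation in gauge records (the trend fit is a plain linear
model, so AR(1) structure is out of scope), within-source correlation of
site CAR (exposed as `within_source_sd`, default 0, since the
compilation's value is unknown), and any covariance between C density and
SAR within a site. Passing tests therefore demonstrate the correctness of
the accounting and inference machinery under the stated statistical
structure, not the field realism of any particular number.

Geography is schematic: seven bounding boxes spaced so that 100-km
neighborhoods do not leak across regions. All randomness derives from one
root seed through named substreams (layout / sites / gauges / inventory /
scenarios), so partial pipelines are reproducible and a fixed seed gives
byte-identical CSV output. Scenario per-segment jitters are drawn before
the scenario id is used, so severity ordering holds per segment for every
seed.

## Problem sizes and numerical choices

Defaults are 50 sites and 200 polygons per region and 42 gauges — enough
for stable regional statistics and non-trivial radius queries while the
full pipeline runs in seconds; the distance matrix is chunked to bound
memory on larger inventories. Tests use 10⁵-draw Monte-Carlo oracles for
error propagation, 200-replicate recovery studies for slope and trend
estimation, and R's base `aov`/`TukeyHSD` (via Rscript) plus permutation
nulls as independent statistical oracles. Solver tolerances: Brent 1e-10
on the correlation calibration; trend fits are closed-form OLS. Degenerate
inputs (constant MSL, zero-variance groups, empty profiles, all-identical
RSLR) raise typed errors rather than returning NaN.

## Known limitations

* The E1 independence assumption across polygons overstates precision of
  interpolated totals; the cluster-aware variant gives a conservative
  alternative but no spatial covariance model is attempted (no kriging).
* The 30→60-yr bridge is a single national regression; stations with
  atypical decadal phase are knowingly mis-mapped, and no station-level QC
  beyond coverage is applied.
* The projection treats RSLR paths as fixed and linearizes the CAR
  response; bands are therefore lower bounds on predictive uncertainty.
* The salt-marsh LOI→TOC quadratic as printed (0.04 linear term) yields
  lower TOC than the 0.40 variant of its original source; both are one
  parameter away (`quad_a`).
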