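# Methods

## Problem and model

The package estimates the association between residential proximity to a
land-use class and an individual's blood biomarker concentration. Exposure
is *buffered parcel area*: the total ground area (m²) of parcels of the
class intersecting a disc of radius 500 m (configurable; 1,000 m is a
common alternative) centred on the participant's residence point, taken as
the centroid of their postcode. Footprint outside the disc is not counted;
overlapping parcels of the same class are unioned before clipping so
shared ground is never double-counted.

The estimating equation is a linear fixed-effects model

    y_ic = β · Exposure_ic + γᵀ x_i + δ_c + ε_ic ,

with β in ng/mL per 1,000 m² of buffered area, x_i individual covariates,
and δ_c an absorbed intercept per administrative area. Two granularities
are exposed: planning-area fixed effects (Model 1) and subzone fixed
effects (Model 2, the headline model); Model 3 adds household income at
the cost of listwise-deleted missing values. The identifying assumption is
that, within an administrative area, any systematic variation in the
outcome that is not due to the exposure is captured by the measured
covariates or the area intercept.

### Inference

Standard errors are the CR1 cluster-robust sandwich with clusters at the
planning-area level:

    V = c · (XᵀX)⁻¹ (Σ_g S_g S_gᵀ) (XᵀX)⁻¹ ,   S_g = X_gᵀ u_g ,
    c = [G/(G−1)] · [(N−1)/(N−K)] ,

where K counts the regressors *including* the absorbed fixed-effect
intercepts. Confidence intervals and p-values use Student-t with G − 1
degrees of freedom. This pairing was chosen because it reproduces, to the
printed precision, published interval bounds reconstructed from their
(β, SE, G) triples — a normal quantile does not — and because with every
observation its own cluster it collapses exactly to HC1, which the tests
assert. When a whole cluster is removed (planning-area jackknife), the
refit's df is (G−1)−1 automatically. Singleton clusters are allowed and
contribute their own score outer product; a warning fires when more than
10% of clusters are singletons.

### Standardized effects

`standardized_coefficient` converts the slope to per-SD units:
β × SD(exposure) in ng/mL per SD, optionally divided by SD(outcome) for
the SD-per-SD coefficient. SDs use the n−1 denominator and are taken from
the analysis sample rather than hard-coded, since reported exposure SDs
vary with sample and vintage (≈10,000–11,900 m² in the motivating study).

## Geometry

Coordinates are planar Cartesian meters in a synthetic frame that mirrors
a projected national grid; there is no geodesy anywhere. The disc is a
regular 256-gon whose vertex radius is inflated by √(θ/sin θ), θ = 2π/256,
so its area equals πr² exactly; a plain inscribed 256-gon would carry a
systematic −0.0100% area bias, right at the documented 0.01% budget, while
the area-matched polygon leaves only local boundary wiggle. Clipped areas
are validated two ways: a closed-form half-disc (0.1% tolerance) and a
Monte-Carlo point-membership oracle (50 random scenes, 4×10⁶ points,
0.5% tolerance; scene parcels are sized so the intersection is a
substantial share of the disc, keeping the binomial sampling error of the
oracle itself near 0.1%). Nearest-facility distance is Euclidean
point-to-polygon distance, zero inside a parcel, and is validated against
a boundary-densification search.

## The synthetic city

The generator defines the study conditions and is first-class, tested
code. Defaults mirror the cohort setting the package emulates:

| parameter | default | meaning |
|---|---|---|
| planning areas / subzones | 33 / 147 | two-level hierarchy; subzones are "neighborhoods" |
| extent | 30 km × 20 km | planar rectangle |
| participants / postcodes | 784 / 500 | several participants share a postcode centroid |
| kiosk footprints | 160 × U(1,000, 4,000) m² | small petrol stations |
| depot footprints | 64 × U(10,000, 50,000) m² | large bus depots/terminals |
| β (true) | 0.15 ng/mL per 1,000 m² | generating slope |
| intercept / σ_ε | 20 / 8 ng/mL | keeps the outcome in the observed PFBS range (median ≈ 18–23 ng/mL) |
| σ_subzone | 2 ng/mL | iid neighborhood heterogeneity |
| subzone confounding | 0.10 ng/mL per 1,000 m² of subzone-mean exposure | see below |
| mover fraction | 0.5 | participants whose future residence differs |

Geography is a recursive slice-and-dice rectangular tessellation — exact
nesting and pairwise disjointness by construction. Parcels are rectangles
with random aspect ratio in [0.5, 2], placed by rejection sampling with
same-class disjointness; requested class area above 25% of the extent, or
a failed placement after 2,000 attempts, raises an error naming the class.
Parcel counts were chosen so that roughly a quarter of residences have any
transport exposure within 500 m and ~50 exceed 12,000 m², giving the
threshold sweep a realistic thinning exposed group.

Subzone intercepts — not planning-area intercepts — carry the spatial
confounding: δ_s = σ_subzone·z_s + 0.10 × (subzone mean exposure, per
1,000 m²). Planning-area FE fits are therefore visibly biased upward while
subzone FE fits are unbiased, exercising the granularity contrast the
model family exists for. The secondary analytes (PFBA, PFNA, PFOA) are
generated on their own concentration scales with proportionally scaled
covariate and neighborhood effects; PFBA's scale (mean 0.9, σ 0.45 ng/mL
against LOD 0.41 / LOQ 0.5) deliberately fails the 95% detection filter so
the filter path is exercised by the default panel.

One master seed feeds independent named substreams (geography, parcels,
postcodes, participants, outcome noise) via `SeedSequence` spawn keys, so
redrawing outcomes or people never perturbs the map. Replicate studies
reuse the geometry through a postcode-level exposure cache.

### Mobility and the negative control

Movers' future postcodes are uniform over other postcodes by default, so
future-residence exposure is null by construction and the negative-control
test's rejection rate estimates its type-I error (≈0.05, checked over 500
replicates). The confounded-preference variant draws a latent factor u_i
per participant, adds λ·u_i to the outcome (λ = 3 in the demonstration)
and samples movers' future postcodes with log-weights 1.5 · u_i ·
z(postcode exposure); the test then rejects far above α, demonstrating
detection of residence-choice confounding. These two constants were set to
give a clearly separated demonstration (power near 1) rather than a
marginal one.

### What the generator does not emulate

Real parcel shapes (rectangles only), road networks and commuting,
spatially clustered sociodemographics (covariates are iid across
residences), skewed/lognormal biomarker distributions, assay batch
effects, and any correlation between covariates and residence choice in
the default DGP. Passing tests therefore show the estimators and plumbing
are correct under the stated DGP, not that the scientific findings
transfer to any real cohort.

## Biomarker preparation conventions

Below-LOD values are substituted by LOD/√2; between LOD and LOQ, values
are retained as reported; at or above LOQ, untouched. The detection filter
keys on the fraction at or above the *LOQ* (≥ means retained at exactly
the 95% boundary); since LOQ ≥ LOD this implies LOD detection, and the
report carries both fractions so the alternative LOD-based reading is
auditable. Percentiles use linear interpolation between order statistics;
SDs use n−1. Simulated instrument readings are floored at zero (the
linear-normal DGP can go negative); the uncensored draw is kept in a
`true_value` column for oracle tests only.

## Dose–response sweep

Thresholds default to 0…20,000 m² in 2,000 m² steps; the indicator is
strictly `area > t`. Thresholds with an exposed group smaller than 50 (or
empty, or the full sample) are *flagged* with a reason but still fitted
when feasible — annotation rather than exclusion, with both behaviors
available via `min_exposed`.

## Replicate study sizes

Chosen as the package's own validation design: recovery and coverage, 200
outcome redraws on the fixed default city; step detection, 100 replicates
of a DGP in which only footprints ≥ 10,000 m² emit (β = 0.3), detection
meaning the mean sweep estimate over t ≥ 10,000 exceeds that over
t < 4,000; negative-control calibration, 500 mobility/outcome redraws
(power variant, 60); jackknife detection, 100 replicates with a planted
local slope of 1.5 ng/mL per 1,000 m² in the subzone with the largest
within-subzone exposure spread. Coverage checks use the band [0.92, 0.98]
around the nominal 0.95, the conventional Monte-Carlo tolerance at these
replicate counts.

## Known limitations

- Exact circular-arc clipping is not implemented; the 256-gon error,
  though far below the stated budget, is not zero.
- The within estimator assumes strictly exogenous exposure given the
  fixed effects; no spatial-error or mixed models are provided.
- Single-value LOD/√2 substitution, not censored-likelihood or multiple
  imputation — matching the convention of the analyses the package
  reproduces, not best current practice for heavily censored analytes.
- The jackknife reports influence; it is not a formal outlier test. The
  permutation-style reference in the tests is a sanity bound, not a
  calibrated null distribution.
- In the movers-only negative-control fit, the absorbed subzone
  intercepts are a large share of N, so the CR1 factor (N−1)/(N−K) is
  well above one and the test runs conservative: its empirical type-I
  error sits at or below the nominal α, varying with the city draw.
  A conservative negative control under-flags confounding; it does not
  over-flag it.
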