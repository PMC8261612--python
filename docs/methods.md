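# Methods

## Model

The estimand is the county abortion rate per 1000 female residents aged
15–44 and its dependence on travel distance to the nearest abortion care
facility. Counts are Poisson with a log link and an offset of
log(P_i/1000), so the intercept and all contrasts live on the log-rate-per-
1000 scale. Fixed effects are seven county covariate proportions (linear),
the six-level travel-distance category (treatment-coded, reference <5
miles) and the five-level state policy grade (treatment-coded, reference =
best grade present in the data). Residual spatial structure is absorbed by
a Markov-random-field smooth: one effect f_i per county with the
graph-Laplacian penalty λ·fᵀSf, S = D − A over the county adjacency graph,
which penalizes squared differences of f across neighbouring counties.

Assumptions worth stating plainly: counts are conditionally Poisson (no
overdispersion beyond the field), women obtain care at their nearest
facility, the covariate effects are log-linear, and the distance effect is
captured by the category a county's median distance falls in. None of
these are tested by this package beyond what the diagnostics show.

## Fitting

Penalized IRLS. Each iteration solves the weighted penalized least-squares
system on the working response. The sum-to-zero constraint on the field
(one constraint per connected component of the graph) is enforced exactly
by augmenting each solve with the constraint rows (a KKT system); this is
numerically equivalent to iterating solve-then-project but does not
perturb the deviance, so step-halving preserves a monotone decreasing
penalized deviance. Convergence is declared when the relative change of the
penalized deviance falls below `tol` (default 1e-8); non-convergence is
flagged on the result, never silent.

A tiny ridge (1e-8 on fixed effects, 1e-8·(1+λ) on the field block) keeps
the system nonsingular: it resolves the intercept/field null direction of
the Laplacian, regularizes category dummies that are empty in a
cross-validation fold (their coefficients shrink to zero and the county
falls back to the reference level), and bounds the conditioning at very
large λ. At λ → ∞ the field vanishes and the fixed effects agree with an
unpenalized Poisson GLM; at λ = 0 without the field block the solver *is* a
Poisson GLM — both equivalences are tested against independent oracles
(statsmodels GLM; the closed-form generalized-ridge solution in the
Gaussian-identity limit).

Standard errors come from the inverse penalized information matrix,
conditional on λ (no smoothing-parameter uncertainty); Wald intervals.

## Hyperparameter selection

λ is chosen on a log-spaced grid (default 10^−2…10^6, 13 points) by
state-grouped cross-validation: folds are states, because missing county
data in the real problem arise from whole states not reporting, and
held-out counties should be spatially and administratively coherent. The
training penalty is the Laplacian of the subgraph induced on training
counties; held-out field values are the harmonic extension of the fitted
field on the full graph (the penalty-minimizing values given the fitted
neighbours; zero for counties with no fitted connection). The fold score is
the MSE of predicted versus observed rates per 1000 — the rate scale
because the plausibility screen and all headline quantities are rates. A
grid point any of whose held-out predictions exceeds 100 per 1000 is
disqualified. Ties in CV-MSE resolve to the smallest λ, then snap-grid
order. Each grid point also records a residual-autocorrelation diagnostic:
Moran's I of the pooled held-out rate residuals on the observed-county
subgraph (the final fit's deviance-residual Moran's I is computed
separately). When the adjacency is built by centroid distance, the snap
threshold enters the same grid search; contiguity graphs ignore it.

## Prediction policy and scenarios

Counties inside the convex hull of the observed county centroids (boundary
counts as inside, so observed counties are inside their own hull) are
predicted with the full model, using harmonic extension for counties not in
the fit; outside the hull the field term is dropped and the covariates
alone predict. Policy grades unseen at fit time are merged with the nearest
worse grade present (e.g. D→F), with a logged warning.

Scenario caps must be category cut points. A cap of 5 sends every county to
the reference category; a cap of 30 recodes categories at or above the cap
to 15–<30 — the highest category strictly below the cap, the most
conservative recode consistent with "all travel under 30 miles" (an
alternative would redistribute capped counties over all sub-cap
categories). Aggregates keep full precision internally; report tables round
counts to the nearest 10 and rates to one decimal.

## Data preparation rules

* **State reconciliation.** If a state's summed observed county counts
  disagree with the independent reference total by more than 1% (relative),
  counts are scaled proportionally and re-integerized by largest remainder
  (ties to the lowest county index), so the state sum equals the reference
  exactly; suppressed and missing counts are untouched and excluded from
  the reported sum. The rule is idempotent. The reconciliation method is a
  design choice; replacement by external county shares would be an
  alternative.
* **Suppression imputation.** A count suppressed below limit L becomes L/2
  unless that implies a county rate above the state mean, in which case it
  stays missing. "State mean" is the pooled rate 1000·Σy/ΣP over the
  state's observed counties, frozen before imputation — stable for small
  counties, unlike the unweighted mean of county rates (the other
  defensible reading).
* **Exposure.** Tract-to-facility distances use a pluggable metric: planar
  Euclidean on synthetic maps, haversine for lon/lat, or a precomputed
  tract×facility table for externally routed road distances (the realistic
  use). County medians are population-weighted (smallest distance at which
  cumulative tract population reaches half the county total); an unweighted
  median is the other reading of "median travel distance per county".
  Excluded tracts (no residents / institutionalised-male-only) never
  contribute. The travel-time sensitivity analysis reuses the same
  machinery on a time column with its own cut points (default 10/30/60/120/
  240 minutes).

## Synthetic-data generator

The generator emulates the study design, not US geography. Counties are
cells of a near-square planar grid; consecutive runs of a boustrophedon
enumeration form states, so states are contiguous blocks and state-grouped
folds are spatially coherent. Tracts scatter around county centroids with
heavy-tailed populations (lognormal, σ = 1.2) amplified near randomly
placed urban centres; facilities locate at high-population tracts
(probability ∝ pop^1.5), reproducing the urban-access gradient that makes
distance and population density correlate. Default scale: 48 states ×
55–75 counties (~3100 counties, ~50 M women), 27 reporting states
(nonreporting fraction 21/48), 7 reporting states suppressing counts below
10, grid extent 1500 miles, 260 facilities — chosen so county populations,
the six distance categories, rates (~10–15 per 1000) and suppression all
take realistic values simultaneously.

The latent field is a proper CAR draw with precision ∝ D − ρA, ρ = 0.95
(the intrinsic MRF the model fits is improper and cannot be sampled),
centred per component and rescaled to an exact standard deviation
(default 0.3). True distance contrasts default to the published adjusted
dose-response values (−0.05, −0.22, −0.34, −0.43, −0.73) read as log-rate
contrasts; the published table is ambiguous between log-rate contrasts and
absolute rate differences per 1000, and this package takes the former
(consistent with a log-link model with a reference level of 1) without
claiming to resolve the ambiguity. Covariate slopes and grade effects are
invented but moderate; the intercept (3.8) puts reference-category rates
near 21 per 1000 at typical covariate values. State reference totals are
true totals with ~5% lognormal noise so the >1% reconciliation rule
actually fires.

What the generator does *not* emulate: road networks (distances are
planar), demographic microdata, spatially varying covariate–outcome
confounding, overdispersion, and reporting error within states. Passing
recovery tests therefore show the estimator recovers its own generative
model at realistic scale — not that the published coefficients are correct.

## Numerical choices and edge cases

Half-open distance bins ([lo, hi), so 5.0 → "5–<15"); negative distances
rejected. Weighted median = smallest value reaching half the cumulative
weight (lower median under equal weights). Nearest-facility ties break to
the lowest facility id. Moran's I uses binary weights with global
normalization by default (row-standardized available); constant input
raises rather than returning 0. Hull membership uses the facet equations
with tolerance 1e-9 × coordinate scale; fewer than three non-collinear
observed points is an error. Zero populations are invalid records, not
zeros. All randomness flows through explicit integer seeds; identical
(config, seed) reproduces byte-identical artifacts.

## Problem sizes used in the test-suite experiments

Parameter recovery runs 20 replicates at ~1500 counties in 27 states (the
scale of the modelled study population). The CV-behaviour experiment runs
20 replicates at ~200 counties in 10 states with an 8-point λ grid and a
strong field (sd 0.5) — a size at which the experiment is informative while
the whole suite stays quick. The acceptance script runs one full
default-scale study (~3100 counties) end to end.

## Known limitations

Confidence intervals are conditional on λ; no uncertainty is propagated
from smoothing-parameter selection, and scenario totals carry no intervals.
Quasi-Poisson/negative-binomial dispersion, REML/GCV smoothing selection
and non-MRF smooths are out of scope. Alaska/Hawaii-style non-road travel
and the construction of the policy grade itself are not modelled. The
cap-30 recode choice and the weighting of the county median are documented
design decisions, not established facts about the original analysis.
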