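# Methods

## Data model

One row per accepted species: first valid description year (≥ 1753, the
start of binomial nomenclature; `discovery_time = year − 1753`), genus,
genus-level growth form, and the set of occupied provinces.  Growth form is
one of four categories — fern, herb, tree/shrub, vine/liana — assigned at
genus level as the modal form among the genus' species; ties break
lexicographically on the category name so assignment is deterministic.
Provinces carry area (km²), population density (persons/km²), a coastal
flag, centroid coordinates, and a symmetric contiguity adjacency (28
merged provincial units in the reference configuration).

Per-species predictors are derived from occupancy alone: range size =
number of occupied provinces (a summed-area variant is available via
`range_metric="area"`; counts are the default because provinces are the
only spatial unit in the data), coast = 1 iff any occupied province is
coastal, and the bounding max/min latitude/longitude of occupied-province
*centroids* (no polygon geometry is used).  Range size is natural-log
transformed; all continuous predictors are then min–max standardized to
[0, 1] **over the subset actually fitted** — an endemic-only rerun
re-standardizes — so coefficients are comparable effect sizes within a
fit.  Tree/shrub is the growth-form baseline (no indicator column).

## Survival stage

With no censoring (only described species are observable), the empirical
survival curve is one minus the scaled accumulation curve, and the Cox
partial likelihood is maximized by Newton–Raphson with step-halving
(relative log-likelihood tolerance 1e−9, 50-iteration cap).  Description
years are annual, so ties are massive: Efron's approximation is the
default; Breslow is implemented for cross-checks and agrees exactly when
no ties exist.  The per-event-time Efron corrections are vectorized with
scalar moment sums over the tie index, so a fit costs O(n·p²) per
iteration.  Standard errors are Wald from the inverse observed
information; constant covariates raise (no information), and |β| > 20 is
flagged as likely separation.

Diagnostics: Harrell's concordance with half-credit for tied scores and a
Noether-type SE (asymptotic U-statistic variance `4·var(c_i)/n` of the
per-subject concordant fractions); scaled Schoenfeld residuals
(`β̂ + n·I⁻¹·r_i`, with risk-set means at each event time) with a
zero-slope test of residual against event time per covariate — the
operationalization of "β(t) looks flat"; Kaplan–Meier curves per stratum
(exact, since every subject is an event); Tukey's range test on mean
discovery times among growth forms; and a generic backward-AIC model
selector shared with the spatial stage (drop the term whose removal most
lowers AIC; stop when no removal lowers it; empty term set = null model).

## Richness stage

Description years are binned into half-open 5-year intervals anchored at
1753.  Years ≥ 2000 (configurable) are excluded from fitting — recently
described species enter catalogs with delay, biasing the curve tail down —
but are tallied and added back to the completeness numerator.  The model

    ΔS_t = (a + b·S_t)(S_tot − S_t) + ε_t

is fitted by bounded trust-region least squares with multi-starts over
S_tot ∈ {1.1, 1.5, 2, 4} × observed (bounds [observed, 20 × observed];
a seeded from the early-curve slope, b from the peak increment), because
the SSE surface is nearly flat in S_tot for pre-inflection curves.  At
least six non-empty bins are required.

Numerical choices that matter:

* The Jacobian's a/b/S_tot columns differ by orders of magnitude, so the
  normal equations are equilibrated (columns scaled to unit norm) before
  pseudo-inversion; without this the S_tot variance is silently truncated
  to ~0.
* The Wald covariance is heteroscedasticity-robust (sandwich): bin counts
  have variance roughly proportional to their mean, and the
  constant-variance covariance is anticonservative in mid-curve bins.  In
  calibration runs (Poisson noise, S_tot = 2000, curve ~75% saturated at
  the cutoff — the regime the flora's completeness estimates suggest) the
  robust interval covers the truth in ~90% of runs versus ~82% for the
  constant-variance one.
* "Generalized" residual structure: iid is the default; an AR(1) option
  estimates ρ from the lag-1 autocorrelation of the iid-fit residuals and
  refits on Prais–Winsten-whitened residuals.  A seeded residual
  bootstrap CI is available (`n_boot`).

Completeness = described / Ŝ_tot, clipped at 1 with a warning.  Both
numerator conventions — described before the cutoff, and described through
the horizon — are always reported side by side (the printed completeness
columns of published versions of this analysis are not mutually consistent,
so neither convention is silently preferred); the through-horizon ratio is
the headline.  The estimator is conservative: when description effort
declines late in the record, the curve flattens for reasons the model can
only read as saturation, and Ŝ_tot tends toward the described count (see
Limitations).

## Spatial stage

Province summaries: species count, mean discovery year, and a weighted
mean with w_i = 1/range_size so widespread species do not dominate.  The
permutation null shuffles the year vector across species (uniformly,
without replacement) while holding occupancy and weights fixed — 1,000
shuffles by default, z = (obs − null mean)/null SD, |z| > 1.96 flagged;
an exact enumeration mode over all n! assignments exists for small n and
is used to verify the sampler.  z-scores are invariant to shifting all
years by a constant.

Moran's I uses binary contiguity weights, row-standardized by default
(binary available), expectation −1/(n−1), and a two-sided permutation
p-value.  It is applied to mean discovery year and to the OLS residuals
(the spatial-independence check justifying plain OLS).

Both explanatory regressions use [0,1]-standardized predictors (binary
terms left as 0/1) and the shared backward-AIC selector, with candidate
terms: species count, coastal flag, population density, area, centroid
longitude and latitude.  Mean discovery year is modelled by OLS (response
in calendar years, matching the convention that puts the intercept near
1900).  Completeness is modelled by logit-link beta regression fitted by
maximum likelihood (statsmodels `BetaModel`), with boundary responses
compressed by the standard (y·(n−1) + 0.5)/n adjustment, Wald CIs, the
precision φ reported on the natural scale, and pseudo R² = squared
correlation between the linear predictor and logit(observed).  Provinces
whose richness fit failed are excluded from the beta regression with a
logged count.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the reference study conditions: per-form species
pools (fern 2,712; herb 23,867; tree/shrub 12,998; vine/liana 1,710),
log-hazard coefficients equal to the reference effect sizes (range +0.51,
coast +0.13, max lon +0.90, min lon −0.46, max lat +0.67, min lat −0.73,
fern −0.82, herb −0.13, vine −0.13), 28 provinces on a 7 × 4 lon/lat grid
with rook contiguity, an eastern coastal column, and a log-linear home-
province gradient (−0.12/° lat, −0.04/° lon) concentrating richness in
the southwest.  Ranges are contiguous: geometric size (mean 3 provinces)
spread at random from the home province over the adjacency graph.
Endemism is Bernoulli(0.42).

Discovery years are drawn by inverse-CDF sampling from a proportional-
hazards law with a piecewise-constant baseline over 5-year blocks shaped
as a Gaussian pulse (peak 1900, SD 55 years — description effort rising
through the 19th century and declining later), normalized so the
integrated baseline hazard is ~1.05 at scale 1, which describes roughly
three quarters of the default pool by the 2013 horizon.  Species
undescribed at the horizon are dropped from the catalog and counted in the
truth record — they are the ground-truth undiscovered pool.

The truth record stores the generating coefficients both on the pool
standardization and mapped onto the min–max scale of the *described*
catalog (an affine rescale; the shift is absorbed by the baseline), so
recovery tests compare like with like.

Tests and the acceptance script run the generator scaled down (total pools
of ~2,000–3,200 species, preserving the default form proportions); these
are the package's chosen experiment sizes.  What the generator does *not*
emulate: polygon range geometry, phylogenetic structure among genera,
taxonomic synonymy, and any dependence of description effort on covariates
beyond the proportional-hazards form.

## Design decisions on genuinely open points

* Range-size unit: occupied-province count (area sum optional) — provinces
  are the only spatial unit available.
* Species coordinate extremes are over province centroids, not polygon
  bounding boxes (no geometry source exists in the data).
* Growth-form tie-break: lexicographic, for determinism.
* Concordance SE: Noether-type pairwise estimator (no formula is standard
  in the reporting convention this mirrors).
* The Schoenfeld "horizontal trend" check is a slope test, not a visual
  judgement.
* Moran weights row-standardized by default; the choice is configurable
  because conventions differ.
* Stratified survival curves are plain Kaplan–Meier per stratum (the
  no-shared-covariate mode); covariate-adjusted stratified fits can be
  obtained by fitting the Cox model per stratum.
* Pipeline stage seeds derive from the master seed by fixed offsets and
  are recorded in the manifest.

## Limitations

* **Truncation attenuates Cox coefficients.**  An all-events Cox fit to a
  catalog missing its undescribed species estimates effects *conditional
  on description by the horizon*; large coefficients attenuate (in
  generator runs with ~75% description, the fern effect shrinks from
  −0.82 toward ~−0.3).  This equally affects any real catalog: the fitted
  effect sizes describe the described flora.  Parameter-recovery tests
  therefore run the generator with a baseline strong enough to describe
  essentially the whole pool.
* **Richness estimates are conservative under waning effort.**  When the
  baseline description pulse declines after its peak, the logistic model
  reads the flattening as saturation and Ŝ_tot tends to the described
  count (overall completeness near 1 even when 20% of the pool is
  undescribed).  The same caveat applies to the real-world analysis this
  mirrors; the acceptance output reports the realized relative error.
* The beta regression's pseudo R² is a correlation measure, not a
  likelihood ratio; model comparison should use the reported AIC.
* No censoring support, no synonym-to-valid-name transition modelling, no
  cartographic output.
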