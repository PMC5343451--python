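# Methods

## Statistical model

The response is site-level population density D (animals/km²) of a
wide-ranging mammal, modelled on the natural-log scale with ordinary
least squares:

    ln(D + c) = β₀ + Σ_j f_j(x_j) + ε,   ε ~ N(0, σ²)

where each covariate x_j enters through its standardized column z_j
(centered, unit SD over the analysis records), and f_j is either
β_j z_j (linear) or β_j z_j + γ_j q_j with q_j the re-standardized
square of z_j (quadratic; used where the predicted relationship is
curvilinear — potential evapotranspiration and agriculture in the
default roster).  The offset c (default 1.0) makes the log defined for
the zero-density background records; c = 1 maps them to response 0.
Because the offset is a modelling choice with no canonical value, it
is configurable and always reported, never silently applied.

Density records are planar (x, y in km); all geometry — buffers, ring
areas, point-in-polygon — is planar via shapely.  This is a deliberate
stand-in for geodesic computation: the procedures under test (ring
construction, proportional allocation, membership predicates) are
geometry-agnostic.

## Data preparation

* **Aggregation.** Multiple estimates for one area (same `site_key`)
  are replaced by their arithmetic mean; coordinates, island flag and
  region tag must agree within a group.  The operation is idempotent.
* **Island/mainland comparison.** A Welch (unequal-variance) t-test
  with Welch–Satterthwaite degrees of freedom, on either raw or
  log-transformed densities.  Both scales are exposed because density
  compilations are strongly right-skewed and the choice materially
  changes t; the pipeline reports both and proceeds with mainland
  records only when islands are significantly denser.  A
  summary-statistics variant (means, SEs, group sizes) supports
  published-table inputs.
* **Background sampling.** The background region is the ring between
  the 100 km and 1000 km planar buffers of the native-range polygon.
  The number of zero-density points is
  round(n_native × area(ring)/area(native)) (half-up rounding — no
  canonical rule exists, so the simplest deterministic one is used),
  drawn uniformly over the ring by rejection from its bounding box.
  Background points are excluded from the island comparison and
  included in the regression with density exactly 0.

## Covariate engineering

* **Focal mean.** A cell's neighborhood is every cell whose *center*
  lies within the radius of its center, inclusive (≤).  The inclusive
  cell-center rule is fixed so that an explicit brute-force disc
  enumeration agrees exactly; NODATA cells are excluded from their
  neighbours' means and a fully-NODATA neighborhood yields NODATA.
  A radius below the cell size reduces to the identity.
* **Scale and form selection.** Per covariate, a univariate model is
  fit at every candidate radius (10/20/40 km supported; the defaults
  use 10 and 40 — the intermediate scale is configured but unused by
  the default roster), with a quadratic companion fit where allowed.
  The (radius, form) pair with minimal AICc wins; ties break toward
  the smaller radius, then the linear form.  The quadratic form is
  accepted exactly when its AICc is lower than the linear form's.
* **Correlation pruning.** While any retained pair has
  |Pearson r| > 0.70, the worst pair is resolved by dropping the
  member with the smaller absolute univariate t-statistic against the
  response.  Expert-judgment exclusion criteria are not mechanizable,
  so a deterministic statistical priority substitutes; the returned
  log of (dropped, kept, r) triples makes each decision auditable.

## Multimodel inference

* **K convention.** K = intercept + slope coefficients + residual
  variance.  Under this convention a model with eight slope columns
  has K = 10, and published selection tables for the global wild pig
  analysis are internally consistent: AICc recomputed from the printed
  log-likelihoods at n = 183 reproduces the printed AICc to 0.01.
* **Enumeration.** All 2^m subsets of term blocks (guarded at 2^20),
  including the intercept-only model; a block's columns enter and
  leave together, so a quadratic term never appears without its main
  effect.  Rank-deficient subsets are excluded and logged.  Gaussian
  ML log-likelihood: logL = −(n/2)(ln 2π + ln(RSS/n) + 1).  An exact
  zero-residual fit (RSS = 0) has no defined log-likelihood and raises
  rather than propagating −∞.
* **Weights.** Softmax of −AICc/2 with a max-shift: deltas between
  model families here reach ~73 AICc units, which underflows a naive
  exponential but is exact under the shift.
* **Averaging.** Default is *full* (zero-substitution) averaging:
  β̄ = Σ wᵢ β̂ᵢ with β̂ᵢ = 0 and varᵢ = 0 in models excluding the term;
  the alternative *conditional* variant (renormalizing over containing
  models) is available via `variant="conditional"`.  The unconditional
  SE defaults to the weighted-sum-of-roots form
  Σ wᵢ √(varᵢ + (β̂ᵢ − β̄)²), with the root-of-weighted-sum variant
  behind `se_form="root-of-sum"` (the two bracket each other by
  Jensen's inequality; sum-of-roots is never larger).
* **Importance.** Summed weight of the models containing a block;
  a block in every model has importance 1 by construction.

A known, measured property of full averaging: for a weak true effect
(standardized β ≈ 0.1 at n = 183, σ = 0.6) the averaged estimate
shrinks toward 0 whenever the sample underplays the term, and the
unconditional SE shrinks with it, so the ±2 SE interval covers the
generating value in only ~84% of replicates versus ~95–98% for the
stronger terms (the recovery test in the suite computes these rates).
This is a property of the estimator, not an implementation defect:
full-model OLS intervals on the same replicates achieve ~97%.

## Prediction mapping

Covariate surfaces are standardized with the *training* means/SDs
(stored in the design table, including the mean/SD of each squared
standardized column), the averaged coefficients are applied on the log
scale, and the map is exp(η) − c floored at 0.  No log-normal smearing
correction is applied by default — the map reads as a maximal
potential density; passing the residual variance as `smearing_sigma2`
applies the exp(σ²/2) mean correction.  NODATA propagates through all
per-cell arithmetic.

The three-class map treats its break anchors (1, 6, 11 animals/km² by
default) as representative class values, not bin edges: edges are the
midpoints (3.5 and 8.5), so any density at or above the top anchor is
guaranteed "high", any at the bottom anchor "low", and classification
is monotone in density.

## Cross-validation

k defaults to Huberty's rule k = ⌈1 + √(p−1)⌉ (p = 7 → k = 4).  Folds
are a seeded random partition with sizes differing by at most one.
Per fold, coefficients are re-estimated on the training part only; by
default the candidate-set structure (memberships and Akaike weights)
is fixed from the full data and only per-model coefficients are refit,
because repeating selection inside folds is a distinct (also
supported: `refit_selection=True`) and more expensive protocol.  MSPE
is computed on the log (model) scale — the scale the model is fit on —
and the pooled observed-vs-predicted Pearson r yields
t = r√(n−2)/√(1−r²) on n − 2 df.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis
assumes: spatially autocorrelated covariate surfaces (Gaussian-kernel
smoothed white noise — the simplest field with a controllable
autocorrelation range; an infinite smoothness scale degenerates to a
constant surface), realistic value ranges per variable (proportions
for cover fractions, mm for quarterly precipitation, an integer 0–6
count for large carnivore richness), a native-range polygon with
small disjoint island patches outside it, a true log-linear density
surface with quadratic terms, log-normal noise, and an island
density multiplier (default 6.7, the ratio of published island to
mainland mean densities).  Default coefficients follow the published
standardized estimates (pet 0.443 with quadratic −0.226, carnivore
−0.243, wet-season precipitation 0.233, unvegetated −0.203,
agriculture 0.236 with quadratic −0.118, dry-season precipitation
0.100, forest −0.001), so recovery experiments are patterned on the
real fit.  Surfaces carry an outward radial trend (conditions
deteriorate away from the range core) so that the background ring is
genuinely unsuitable — the assumption the zero-density procedure
rests on.

Noise calibration: σ = 0.60 was chosen analytically so that, in the
well-specified design-level regime (standardized covariates, n = 183),
the top model's adjusted R² lands near 0.55, the fit regime of the
global analysis (measured ≈ 0.57 over 50 replicates).  The full
landscape pipeline adds structural error the design-level regime does
not have — the ln(D + 1) response versus log-scale truth, background
zeros standing in for small-but-nonzero surface values, focal-mean
attenuation — so its end-to-end adjusted R² is lower (≈ 0.4–0.5).
Passing pipeline tests therefore demonstrate correct plumbing and
qualitatively right inference, not unbiased end-to-end coefficient
recovery; quantitative recovery claims are made (and tested) at the
design level.

Features of real compilations the generator does not emulate: geodesic
geometry and real coastlines, temporal averaging across decades of
source data, spatially biased literature sampling, and measurement
error in the density estimates themselves.

## Problem sizes

Default synthetic runs use an 8000 × 8000 km extent at 10 km cells
(800 × 800 grid) with 118 mainland + 11 island records — a full run
takes a few seconds.  The test suite exercises the pipeline on a
1600 × 1600 km / 20 km landscape, oracle checks on ≤ 12 × 15 grids,
and recovery/CV experiments at n = 183 with 50 replicate seeds.

## Known limitations

* Planar geometry throughout; buffer distances are Euclidean km.
* Independent-error OLS: no spatial autocorrelation correction in the
  residuals, mirroring the analysis design the package implements.
* Full-model-averaged intervals undercover weak effects (see above).
* The rejection sampler for background points assumes the ring is a
  reasonable fraction of its bounding box; pathological polygons
  (e.g. extreme aspect ratios) will sample slowly though correctly.
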