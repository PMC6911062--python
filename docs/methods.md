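# Methods

## Models

**Sampling process.** The opportunistic sampling locations are modelled
as a log-Gaussian Cox process with intensity
Λ(x) = exp{α₀ + α₁D(x) + α₂V(x) + S(x)}, where D is distance to the
collectors' home (km), V the value-of-nature covariate and S a zero-mean
stationary Gaussian field with Matérn correlation (variance σ², scale φ
km, smoothness κ).  κ is fixed at 1 and never estimated: variance, scale
and smoothness cannot all be estimated consistently from one realization
on a bounded domain, so smoothness is treated as a modelling choice.
The likelihood is discretized: the latent field takes one value per grid
cell and the point pattern is reduced to cell counts, each cell
contributing a Poisson term with mean `area · exp(linear predictor)`.
This converges to the continuous point-process likelihood as the grid
refines; a `refine` factor subdivides the covariate grid for the latent
field while covariates stay at native cell resolution.  Discretization
stability is asserted in the acceptance suite (halving the cell size
moves each intensity coefficient by less than its standard error).

**Richness.**  Counts are conditionally Poisson given a spatial field
U (exponential correlation: variance ν², scale ψ) shared by records in
the same cell, and a per-record nugget Z ~ N(0, τ²).  The opportunistic
(CSD) linear predictor carries the covariates W/V/F, log collector
count, a cubic B-spline in year, and the plug-in adjustment γŜ(x); the
randomized (RSD) predictor carries W/V/F and a linear year effect
centred at 1997.  Ŝ enters as a *fixed* covariate computed from the
LGCP fit; its estimation uncertainty is not propagated.  This mirrors
the two-stage design of the analysis the package implements and is a
known limitation: γ̂ is attenuated relative to the dependence on the
true field (the synthetic generator injects dependence through the true
S, so recovery tests see this attenuation by construction).

**Comparison.** Predictions are compared only where both sources are
informative: a cell passes if, for *each* source, the fitted correlation
between U_j there and at the nearest sampled location (nearest over the
union of both sources' locations) is at least 0.75.  With exponential
correlation this is a distance cutoff −ψ_j ln 0.75; requiring both
sources intersects the two masks (a cell where only one source is
informative cannot support a comparison).  RD(x) =
(μ̂_CSD − μ̂_RSD)/max(μ̂_CSD, μ̂_RSD) is antisymmetric and bounded in
[−1, 1]; cells where both means are zero are dropped with a missing
marker.

## Estimation

Parameters are estimated in two tiers.

1. **Covariance parameters (σ², φ) or (ν², ψ, τ²)** maximize a
   restricted (REML-type) Laplace marginal likelihood in which the fixed
   effects are integrated out jointly with the latent field under a flat
   prior.  Plain maximum likelihood estimates of variance components
   from a single field realization are biased low — on a domain not much
   larger than the correlation range the data contain only a couple of
   effective replicates of the field — and that bias propagates into
   overconfident coefficient intervals.  The restricted likelihood
   removes most of it (verified by simulation: coefficient CI coverage
   moved from ~0.6–0.8 to ~0.88–0.98).  The optimizer is L-BFGS-B with
   an analytic gradient (envelope theorem plus implicit differentiation
   of the joint mode) and three starts (the profile can have a
   short-range/nugget-dominated local mode).

2. **Regression coefficients** are then estimated by Monte Carlo maximum
   likelihood at the restricted covariance estimate: importance samples
   are drawn from the Laplace approximation of p(latent | data), the
   Monte Carlo likelihood ratio is maximized (analytic gradients), and
   the importance density is refreshed at the new estimate until the
   relative parameter change falls below 1e-3 (default at most 5
   refreshes; the final refresh uses the larger `info_samples` size).
   Agreement of the Monte Carlo likelihood with adaptive Gauss–Hermite
   quadrature (within 3 Monte Carlo standard errors) is asserted on
   small instances for both covariance families.

**Confidence intervals** are Wald intervals.  The coefficient block uses
the GLS-type covariance (Xᵀ(W⁻¹ + Σ)⁻¹X)⁻¹ at the estimate — this
propagates the full latent covariance, including its common-mode
component, into the intercept's uncertainty — plus two corrections for
covariance-parameter uncertainty: a sigma-point average of that
covariance over the restricted-likelihood uncertainty of the covariance
parameters (steps capped at 2 log units so flat nuisance directions
cannot explode), and a first-order Kass–Steffey term for the sensitivity
of the coefficients to those parameters.  The covariance-parameter block
is the inverse observed information of the restricted likelihood
(finite differences of its analytic gradient).  Curvature of the Monte
Carlo objective itself is deliberately *not* used: with a finite
importance sample it understates the posterior score variance and gives
intervals that are far too narrow.

Poisson factorial constants are dropped in every likelihood (engine,
conditional likelihood helpers, and the quadrature oracles the tests
compare against), since only differences matter.

Numerical policies: covariance factorizations retry once with
1e-8 × variance diagonal jitter, then fail; duplicate locations are
valid only with a positive nugget or via deliberate cell-sharing of the
latent value; latent-field bounds keep log-scales within the grid's
resolvable range (cell/4 to a few domain diagonals).

## Prediction

μ̂_j(x, t) = exp(η̂ + m_U(x) + v_U(x)/2), where (m_U, v_U) are the
kriged conditional mean and variance of U at the cell given the latent
posterior at the record locations.  The nugget is excluded by default —
it is record-level noise and the target is the smooth mean surface — and
can be included with a flag.  The standard error is the lognormal form
mean·√(exp(v_U) − 1); a fit with no latent variance therefore has
se = 0 exactly, which keeps the plug-in limit clean.  A delta-method
term for coefficient uncertainty can be added with
`include_param_uncertainty=True` (off by default so the no-latent limit
stays exact).  CSD predictions fix the collector count at 2 by default,
the prediction year at 1998.

The time spline uses the interior knots (1990, 1995, 2000, 2002, 2004,
2006), degree 3, boundary knots clamped at the data range (1985, 2009).
One basis column is absorbed into the intercept; the fitted time effect
is reported relative to its 1997–1999 mean, which makes it comparable
across models without an identifiability ambiguity.

## Synthetic studies

The generator reproduces the statistical structure the analysis assumes,
at desk scale (default 30 × 30 cells of 1 km, standing in for a
provincial survey region of a few thousand km²):

- **Covariates** W, V, F: correlated Gaussian fields (Matérn κ=1,
  scale 5 km — intermediate between the latent scales of the two stages,
  giving realistic smooth maps) pushed through the standard normal CDF,
  so marginals are uniform on [0, 1].  Default cross-correlations
  (0.1, 0.3, 0.3) reflect that wetness, nature value and forest cover
  co-vary moderately in real landscapes.
- **CSD**: cell-wise Poisson point counts under the LGCP truth with
  uniform positions within cells; visit years uniform on 1985–2009 (the
  real temporal coverage is uneven; not emulated); collector counts on
  {1, 2, 3} with probabilities (0.1, 0.8, 0.1) — two regular collectors
  occasionally joined or alone; richness counts from the CSD model truth
  using the *true* S (coefficient γ), the cell-shared U, and per-record
  nuggets.
- **RSD**: a randomly offset 1-km lattice keeping intersections whose
  cell has forest cover ≥ 0.5 (default), years uniform on 1997–1999,
  counts from the RSD model truth.
- Two presets ship: `nonpreferential` (γ=0) and `preferential` (γ=0.5).

What passing tests show — and don't.  Recovery and coverage results are
for data generated *from the model*; they validate the estimation
machinery, not the model's adequacy for real surveys (unreported effort,
species-level detection, uneven temporal coverage and GIS-derived
covariates are all outside the generator).  Desk-scale domains make the
long-range RSD field (ψ=13 km on a 20-km domain) close to
unidentifiable from one realization; the restricted likelihood and the
interval corrections above are what keep coefficient coverage near
nominal in that regime.

## Problem sizes and defaults

Monte Carlo defaults: 2000 importance samples, at most 5 refreshes,
relative tolerance 1e-3.  The simulation studies in the test suite run
at reduced size (300 samples, 600 for the final information stage, 2
refreshes) on 20 × 20 grids with ~60–400 records per replicate, 50
replicates per recovery study, 15 per discrimination arm; the LGCP
recovery intercept is −0.75, giving ~250 points per replicate.  The
acceptance script runs the full pipeline on the preferential preset over
a 20 × 20 km region.  All randomness flows from explicit seeds; the
pipeline splits its global seed into per-stage seeds with
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible.

## Known limitations

- Ŝ uncertainty is not propagated into the richness stage (plug-in).
- Wald intervals on the log covariance parameters are symmetric although
  the restricted profile is flat to the right for long ranges; their
  coverage is reported by the recovery tests.
- The comparison carries no uncertainty band: RD is a point comparison.
- Purely spatial latent fields; time enters only the mean structure.
- Planar Euclidean distances in km; inputs must be in a projected CRS.
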