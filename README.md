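# mossmap

Geostatistical mapping of species richness from opportunistic
(citizen-science) and randomized survey records, with explicit modelling
of where the citizen collectors chose to sample.

Opportunistic biodiversity records are cheap and abundant, but the
locations are chosen by the collectors, not by a design: sites close to
home, or known to be interesting, are visited more often.  When the same
unmeasured factors drive both the choice of location and the recorded
species counts — *preferential sampling* — naive spatial prediction is
biased.  `mossmap` implements a two-stage analysis of this problem for
point-referenced species-richness counts on a regular (1 × 1 km) grid,
as developed for forest ground-floor bryophyte surveys:

1. **Sampling model.** The opportunistic sampling locations are a
   log-Gaussian Cox process,

   Λ(x) = exp{α₀ + α₁ D(x) + α₂ V(x) + S(x)},

   with D(x) the distance to the collectors' home (km), V(x) the
   "value of nature" of the cell, and S(x) a stationary Gaussian field
   with Matérn correlation ρ(u) = {2^(κ−1) Γ(κ)}⁻¹ (u/φ)^κ K_κ(u/φ),
   κ fixed at 1.  The field's predictive mean Ŝ(x) summarizes sampling
   preference not explained by D and V.

2. **Richness models.** Richness counts Y_j(x, t) from source
   j ∈ {CSD (opportunistic), RSD (randomized)} are conditionally Poisson:

   log μ_CSD = β₀ + β₁W + β₂V + β₃F + β₄ log C + f(t) + γ Ŝ(x) + U(x) + Z
   log μ_RSD = β₀ + β₁W + β₂V + β₃F + β₅ (t − 1997) + U(x) + Z

   with W/V/F cell covariates in [0, 1], C the collector count, f(t) a
   cubic B-spline in the survey year, U a Gaussian field with
   exponential correlation (variance ν², scale ψ), and Z a per-record
   nugget (τ²).  The plug-in term γ Ŝ(x) is the preferential-sampling
   adjustment: a nonzero γ signals residual dependence between sampling
   and richness.

3. **Comparison.** Both fitted surfaces μ̂_j(x, 1998) are compared where
   both sources are informative — cells whose fitted correlation with
   the nearest sampled location is ≥ 0.75 — via the relative difference
   RD(x) = (μ̂_CSD − μ̂_RSD) / max(μ̂_CSD, μ̂_RSD) ∈ [−1, 1].

Estimation is Monte Carlo maximum likelihood (Laplace-based importance
sampling) on a regular-grid discretization of the latent fields, with
covariance parameters estimated by a restricted (REML-type) Laplace
likelihood and Wald confidence intervals.  A synthetic-data generator
reproduces the full generative structure (smooth correlated covariates,
LGCP-sampled opportunistic points, a forest-restricted lattice design,
conditionally Poisson counts), so the whole pipeline is testable by
parameter recovery without any data download.

## Worked example

```python
from mossmap import lgcp, pipeline, synthetic

# a complete synthetic study: covariates, opportunistic points, lattice survey
config = pipeline.RunConfig(
    scenario=synthetic.preset("preferential", bbox=(0, 0, 20, 20),
                              home=(5, 10), seed=1),
    seed=1, out_dir="demo_run",
)
artifacts = pipeline.run_full_analysis(config)

fit = artifacts["lgcp_fit"]
print(round(fit.estimates["alpha1"], 3))            # -0.131
print(round(lgcp.intensity_ratio(2.778, 1.0)))      # 16
print(round(artifacts["csd_fit"].estimates["gamma"], 3))   # 0.365
s = artifacts["comparison"].summary
print(s["n_cells"], round(s["min"], 2), round(s["max"], 2))  # 382 0.22 0.95
```

The fitted α₁ ≈ −0.131 says sampling intensity decays with distance
from home (the generating value is −0.1); `intensity_ratio(2.778, 1)`
≈ 16 is the classic worked example — a fully "valuable" cell is sampled
about 16 times more intensely than a worthless one at that coefficient.
γ̂ ≈ 0.37 detects the injected preferential dependence (γ_true = 0.5,
attenuated because the model only sees the estimated Ŝ, not the true
field).  The last line summarizes the relative-difference surface over
the comparable region.

The same pipeline runs from a shell:

```sh
mossmap run-all --seed 1 --out demo_run
mossmap simulate --preset nonpreferential --seed 7 --out bundle/
```

Inputs can also be real files (ESRI ASCII covariate grids, CSV point
and record tables) via a YAML config; see `mossmap.pipeline.RunConfig`.

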