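# Methods

## Viability model

Seed viability under constant-stress aging is modelled as probit-linear
in time: the viable fraction after `t` days is `v(t) = Φ(Ki + b·t)`
with `b < 0`. The probit scale used throughout is the plain normal
equivalent deviate (no +5 offset), so "one probit of viability loss"
corresponds to one standard-normal unit and the time to 50 % viability
is exactly `p50 = Ki·σ` with `σ = −1/b`. Dish counts are treated as
binomial with success probability `v(t)` and sample size equal to seeds
sown; overdispersion between dishes is absorbed by a quasi-likelihood
dispersion factor rather than modelled parametrically.

## Fitting

Point estimates maximize the binomial likelihood via iteratively
reweighted least squares on the probit link with prior weights equal to
seeds sown. Numerical choices:

- start from shrunk empirical proportions, `μ₀ = (count + 0.5)/(n + 1)`;
- cap the linear predictor at |η| ≤ 8 when evaluating means and weights
  (Φ(±8) is within 7·10⁻¹⁶ of 0/1, so the cap only guards against
  overflow in the weight ratio; it is not treated as a convergence
  failure, because genuinely short-lived lots routinely imply η < −8 at
  the longest aging durations);
- stop when the relative deviance change falls below 10⁻¹⁰, cap 100
  iterations;
- a response that is all-zero or all-full at every duration is complete
  separation: the fit is returned with `converged=False` and a
  diagnostic message, never as a silent estimate;
- coefficients smaller than 10⁻¹² in magnitude are treated as numerical
  zero in the Wald test and the σ transform (a noise-free flat lot
  otherwise produces a spurious "significant" slope of order 10⁻¹⁷).

Dispersion is Pearson χ²/(n − p), not floored at 1. All standard
errors, t tests (residual-df t distribution), and the nested model
comparison use it. The nested comparison is the quasi-binomial F test,
`F = (ΔD/Δp)/φ_full` with φ from the full model, against
`F(Δp, df_full)`.

The σ confidence interval maps the slope's t-based Wald interval
through `x ↦ −1/x`, which is monotone on the negative half-line; this
respects σ's positivity and asymmetry, unlike the delta method. When
the slope interval reaches zero the σ interval is unbounded and is
reported as undefined rather than truncated.

## Screening

Lots enter comparative analyses only after four ordered rules:
contamination flag (carried as data; the underlying fungus judgement is
not computational), initial germination ≥ 50 %, a significantly
negative slope (two-sided p < 0.05 — "significant" operationalized as
p < α AND b < 0, since a significantly positive slope is a failed decay
fit), and σ not exceeding the longest aging duration in the design
(beyond which the experiment saw too little of the survival curve).
Initial germination is the maximum replicate-mean percentage over the
0/1/5-day exposures, because a brief heat exposure can break dormancy
and the day-0 value alone would misread dormant lots as inviable. The
first matching rule wins; the σ bound is taken from the design's
maximum duration rather than hard-coded, so simulated designs screen
consistently.

## Species-level analyses

Within-species heterogeneity compares a full probit model (per-lot
intercepts and slopes) against a reduced one (per-lot intercepts,
common slope) with the quasi-F test; the reduced model's shared slope
is the species σ, computed for every species regardless of the test
outcome. Dispersion is estimated per fitted model, not pooled across a
species' lots. Detection of heterogeneity is related to lots per
species by a logistic GLM; both McFadden and Nagelkerke pseudo-R² are
reported since the two conventions differ substantially at these sample
sizes.

## Predictor models

The lot-level mixed model takes ln σ as the response (the log is applied
to both the lot-level and species-level models; a `log_response` switch
preserves the untransformed alternative), with within-species-scaled
seed mass (centered, sample-SD standardized; species need ≥ 2 lots),
MAT and MAP as fixed effects and a species random intercept. Variance
components are REML, profiled over the single ratio λ = τ²/s² on a log
grid with an explicit boundary check at λ = 0 (boundary fits are
flagged singular, not errors). Fixed effects are GLS at the REML
optimum; type-III tests are Wald χ² with 1 df per continuous term and
no small-sample df correction. Lots with any missing covariate are
dropped listwise with a count.

Explained variance uses the random-intercept R² decomposition:
`R²m = var(Xβ)/(var(Xβ) + τ² + s²)` and
`R²c = (var(Xβ) + τ²)/(…)`. Derived shares: species identity alone
carries `R²c − R²m`; the within-species predictors explain
`R²m/(1 − (R²c − R²m))` of the variance left after species identity.

Species-level models are OLS on ln σ with sum-to-zero factor contrasts
and type-III (drop-term) F tests; families represented by a single
species are kept (they still inform the family contrasts), and a
single-family dataset drops the family term with a warning. Species
mean seed mass enters on the log scale, since 1000-seed mass spans two
orders of magnitude across grassland species.

## Synthetic data

The generator inverts the analysis model. Lot ln σ values follow
`ln σ = μ + u_species + family offset + β_MAT·(MAT − mean) +
β_mass·mass_scaled + ε`; dish counts are beta-binomial with intraclass
correlation ρ, the standard generative counterpart of quasi-binomial
variance inflation (`φ = 1 + ρ(n − 1)`). Dormancy is a day-0-only
germination deficit — the simplest mechanism that exercises the
max-over-{0, 1, 5} initial-germination rule. Defaults describe a
plausible multi-species grassland study: median σ 20 days, Ki ≈ 2
probits, ρ = 0.05, β_MAT = 0.03 per °C, β_mass = −0.1 per within-species
SD, species intercept SD 0.5, lot residual SD 0.2, MAT uniform on
5–15 °C, MAP uniform on 500–1000 mm (the MAP range is a pragmatic
addition so lot metadata is complete), lot mass lognormal with CV 0.2
around a lognormal species mean. MAT-uniform and mass-lognormal are
pragmatic shapes; only their moments matter to the analyses.
`variance_share_config` solves for the β and SD values that put the
latent ln σ variance at requested fixed/species/residual shares (e.g.
5 %/67 %/28 %), split evenly between the MAT and mass effects.

What the generator does **not** emulate: fungal contamination dynamics,
seed-moisture physics, spatial or phylogenetic autocorrelation among
origins, correlated MAT/MAP (real climates correlate), or
duration-dependent dormancy beyond day 0. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every feature of field data.

## Test problem sizes

Simulation-based checks are sized to keep the default suite fast while
leaving Monte-Carlo error well inside the asserted tolerances: 2000
replicates for the F-test type-I rate (binomial 95 % band
[0.035, 0.065]), 1000 for mixed-model test calibration, 500 lots for σ
recovery, 300–500 for coverage checks, and 10 end-to-end pipeline
replicates for the R² decomposition (each with 40 species × 5 lots).

## Known limitations

- Only probit-link binomial-type responses and the three design kinds
  are supported; this is not a general GLM framework.
- No profile-likelihood or bootstrap intervals for σ.
- The mixed model supports a single scalar random intercept (species);
  no crossed or nested random effects.
- Under strong overdispersion the σ interval can reach the undefined
  regime (slope interval containing 0) even for lots that pass
  screening on the point estimate; such lots report σ without a CI.
- With ρ = 0.05 overdispersion and the reference design, the
  information floor puts the per-lot σ's median absolute relative error
  near 6–10 % (slope relative SE 9–15 % depending on σ); precision
  claims tighter than that require more seeds or more durations, not a
  different estimator.
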