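# Methods

## The model

Adult human mortality is described by a Gompertz–Makeham hazard with a
fixed multiplicative frailty:

    mu(x, z) = z · a·e^{bx} + c,        x = age − starting age

where `a` (per year) is the level of senescent mortality at the starting
age, `b` (per year) the rate of its exponential increase, `c` (per year) an
age-independent background, and `z` an individual's frailty, drawn at the
starting age from a gamma distribution with mean 1 and variance `γ`
(shape 1/γ, scale γ). Integrating frailty out gives the population
("marginal") hazard

    mu(x) = a·e^{bx} / (1 + (aγ/b)(e^{bx} − 1)) + c,

a sigmoid in age: within-cohort selection removes the frail first, so the
age-dependent part of the population hazard is bounded by b/γ (the
mortality plateau). For γ = 0 the expression reduces exactly to the
homogeneous Gompertz–Makeham hazard.

## Estimation

Death counts are modelled as D(x) ~ Poisson(E(x)·mu(x)) given exposures
E(x), yielding the log-likelihood Σ_x [D(x)·ln mu(x) − E(x)·mu(x)]. The
hazard is evaluated at the mid-point of each one-year age interval
(x + ½), the natural hazard point for the central death rate D/E; the
synthetic-data generator uses the same point, so estimator and generator
share one generative model. Evaluating at the interval start instead would
bias `a` upward by roughly e^{b/2} (≈5% at b = 0.1), comparable to its
sampling error at the scales used here.

The likelihood surface is multimodal and stiff in (a, c, γ), so the fit
runs differential evolution over a box (log₁₀ a ∈ [−6, 0], b ∈ [10⁻³, 1],
c ∈ [0, 0.5], γ ∈ [0, 5] — wide enough to cover all published human
estimates), seeded for reproducibility, followed by an explicit L-BFGS-B
polish. Convergence is judged on the polish; the global phase exhausting
its generation budget is recorded in the trace but is not a failure.
`a` is searched in log space because plausible values span orders of
magnitude. Fits are run separately per starting age (default 40, 50, 60,
70) with the model age origin re-anchored at each; for gamma frailty this
is self-consistent, because the frailty distribution of survivors is again
gamma with the same variance after rescaling to mean 1.

Identifiability degrades with the starting age: at 70 only ~40
high-mortality ages enter, and `c` and `γ` trade off strongly (both bend
the log-hazard). At the default study conditions the asymptotic relative
standard errors at starting age 40 are ≈2% (a), 1% (b), 10% (c), 3.5% (γ);
at starting age 70, γ's sampling noise dominates any age trend in the
estimated heterogeneity fraction. This is why per-cohort results at the
oldest starting age should be averaged, not read individually.

When the estimated γ falls below 10⁻⁵ the population is treated as
homogeneous (a single frailty class, z = 1). With truly homogeneous data
the γ MLE sits on the boundary in roughly half of replicate cohorts (the
estimator is half-normal around 0), so this rule fires for some cohorts
and not others — expected behaviour, not instability.

## Frailty discretization

The gamma frailty distribution is approximated by g = 200 point masses,
log-spaced between the 10⁻⁵ and 0.9999 quantiles. Each node receives the
gamma-cdf mass of its bin, with bin edges at geometric midpoints between
adjacent nodes and the first/last bins extended to 0 and ∞, so the weights
sum to one by construction and refinements are consistent (halving the
spacing changes the moments by less each time). The node vector is then
rescaled so the discretized mean is exactly 1; without this the
discretization bias would leak into the baseline level. At g = 200 the
discretized variance is within 0.05% of γ; the residual error at large g
comes from the fixed upper-tail truncation at the 0.9999 quantile, not
from node spacing.

## The age × frailty chain

Ages are ω = 150 one-year classes, frailty g = 200 classes; the joint
population vector stacks, for each age class, the g frailty abundances.
Survival of class i over [j, j+1) is exp(−mu(z_i, j−1)) — the hazard at
the interval's start, evaluated at model ages 0..ω−2 for the ω−1
transitions — placed on the first subdiagonal of an ω×ω matrix; the last
age class has no outgoing survival (certain death; survivorship to age
150 is far below 10⁻¹⁰ for human parameters, so the truncation is
immaterial). The joint projection matrix is assembled with the
vec-permutation (commutation) matrix K, U~ = K′·diag(U_1..U_g)·K, with an
optional column-stochastic frailty-transition matrix per age class for
dynamic-frailty extensions (identity by default: frailty is fixed for
life).

U~ is substochastic and nilpotent, i.e. the transient part of an absorbing
Markov chain with death absorbing. The fundamental matrix N = (I − U~)⁻¹
gives expected visits; longevity (absorption time, counted in age classes
visited including the starting one) has moment vectors
η₁ = (1′N)′ and η₂ = [η₁′(2N − I)]′, variance V = η₂ − η₁∘η₁.
Because age always advances, I − U~ is unit lower triangular in the
age-block ordering, so η₁ and η₂ are computed by two sparse triangular
solves with (I − U~)′ in O(ωg) memory — at ω·g = 30 000 states the dense
fundamental matrix (7.2 GB) is never formed outside small test models,
where it doubles as the Neumann-series oracle.

## Variance decomposition

Longevity of the starting age class is a mixture over frailty groups with
mixing weights π. By the law of total variance,

    V(η) = π′V(η_groups) + [π′(E∘E) − (π′E)²] = V_within + V_between,

stochasticity (mean of within-group variances) plus heterogeneity
(variance of group means). The reported `fraction_heterogeneity` is
V_between/V(η), NaN (not 0) for a degenerate deterministic chain.
Variances are invariant to the ±1 shift in the visit-count convention;
means are reported both inclusive (`mixture_mean`) and exclusive
(`mean_after_start`) of the starting class. One-year age classes are
assumed throughout, so variances are in years².

An independent Monte Carlo route simulates lifetimes with known frailty
labels: each individual draws a class from π and then an absorption age
directly from the exact discrete absorption-time distribution implied by
the per-class survival probabilities (inverse cdf; the same law as
age-by-age Bernoulli survival, vectorized). The empirical within/between
decomposition over labels, with bootstrap standard errors, cross-checks
the matrix computation in the tests and the acceptance script.

## Synthetic data

The generator emulates national-statistics cohort tables: deterministic
exposures from the marginal-hazard survivorship (trapezoid of l(x) at the
interval endpoints, with the cumulative hazard by adaptive quadrature) and
Poisson death counts with intensity E(x)·mu(x+½). Exposures are expected
person-years, not sampled, because the likelihood conditions on E(x). The
default study condition — a = 0.02, b = 0.1, c = 0.005, γ = 0.2 anchored
at age 40, 10⁶ individuals at the starting age, ages 40–109 — is a
deliberately heterogeneous human-range schedule (remaining life
expectancy at 40 of ≈35 years); with it the heterogeneity fraction at
starting age 40 is ≈0.13, rising to ≈0.18 at 70, and total variance falls
from ≈77 to ≈11 years². Real cohort tables additionally contain migration,
age heaping, war and epidemic shocks, and violations of the
proportional-hazards and gamma-frailty assumptions; passing tests on
synthetic data show the estimator and decomposition are correct under the
model, not that the model is correct for any particular population.

The reader for the standard 1×1 deaths/exposures exchange layout drops
the open "110+" age group: with certain death at age class 150 the tail
contribution is negligible.

## Numerical choices

- Degeneracy threshold γ < 10⁻⁵ → single frailty class; γ = 0 is treated
  identically (avoids the 1/γ gamma shape).
- Marginal hazard evaluated with overflow-safe saturation: once e^{bx}
  overflows, the plateau b/γ + c is returned exactly.
- π is validated, never silently renormalized; a non-probability vector is
  an error.
- V_between is clipped at 0 against roundoff in the single-group case.
- Monte Carlo problem sizes in tests and the acceptance script (10⁵
  lifetimes, 200 bootstrap replicates, 20 fit replicates) put Monte Carlo
  error well below the effect sizes being checked while keeping the full
  suite fast.

## Known limitations

- Fixed frailty only is exercised; the dynamic-frailty hook (per-age
  column-stochastic mixing matrices) is implemented and validated but no
  diffusion model for frailty dynamics is provided.
- No standard errors or profile intervals for the fitted parameters.
- Period tables are analysed as synthetic cohorts through the identical
  pipeline; no cohort–period translation or smoothing.
- Non-unit age-class widths are unsupported.
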