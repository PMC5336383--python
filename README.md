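# frailvar

**How much of the variation in human lifespans is luck, and how much is
built-in difference between people?** Even in a perfectly homogeneous
cohort, individuals die at different ages because survival is a chance
process (*individual stochasticity*). On top of that, individuals may
differ in an unobserved, lifelong mortality multiplier (*heterogeneous
frailty*). `frailvar` separates the two: it fits a
gamma-Gompertz–Makeham (ΓGM) frailty model to cohort death/exposure
tables, builds the corresponding age × frailty absorbing Markov chain,
and decomposes the variance of remaining longevity into a within-group
(stochasticity) and a between-group (heterogeneity) component.

It is aimed at demographers and ecologists working with cohort or period
mortality tables in the national-statistics deaths/exposures format.

## The model

Individual hazard at model age *x* (measured from a starting age) with
frailty *z*:

    μ(x, z) = z·a·e^{bx} + c,    Z ~ Gamma(mean 1, variance γ)

Population (marginal) hazard after within-cohort selection:

    μ(x) = a·e^{bx} / (1 + (aγ/b)(e^{bx} − 1)) + c

The four parameters (a, b, c, γ) are estimated by Poisson maximum
likelihood from death counts D(x) and exposures E(x),
ln L = Σ_x [D ln μ − E μ], via seeded differential evolution plus a local
polish. The fitted model is discretized into g = 200 frailty classes and
ω = 150 age classes and assembled, with the vec-permutation matrix K,
into the transient matrix Ũ = Kᵀ·diag(U₁…U_g)·K of an absorbing Markov
chain. From the fundamental matrix Ñ = (I − Ũ)⁻¹ the moments of longevity
η follow, and the law of total variance splits V(η) over the frailty
mixture π:

    V(η) = πᵀV(η_groups) + Vπ[E(η_groups)] = V_within + V_between

`fraction_heterogeneity = V_between / V(η)` is the headline quantity.
Details, assumptions and numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

```python
from frailvar import (GGMParams, generate_poisson_cohort, fit_ggm,
                      discretize_frailty, matrix_decomposition)

truth = GGMParams(a=0.02, b=0.1, c=0.005, gamma=0.2, start_age=40)
cohort = generate_poisson_cohort(truth, n0=1e6, n_ages=70, seed=7)

fit = fit_ggm(cohort, start_age=40, seed=3)
p = fit.params
print(f"a={p.a:.4f} b={p.b:.4f} c={p.c:.4f} gamma={p.gamma:.3f}")

d = matrix_decomposition(p, discretize_frailty(p.gamma, 200), 150)
print(f"V(eta)={d.v_total:.1f}  V_within={d.v_within:.1f}  "
      f"V_between={d.v_between:.1f}  fraction={d.fraction_heterogeneity:.3f}")
```

prints

```
a=0.0199 b=0.1001 c=0.0052 gamma=0.199
V(eta)=77.3  V_within=67.5  V_between=9.8  fraction=0.127
```

i.e. the fit recovers the generating parameters from one synthetic cohort
of 10⁶ people, the variance of remaining longevity at age 40 is ≈77 years²,
and only ≈13% of it is attributable to heterogeneous frailty — the rest is
individual stochasticity.

The same pipeline is scriptable from the shell:

```bash
frailvar generate --seed 4 --label 1850 --out cohort.tsv
frailvar decompose cohort.tsv --seed 6 --out results.tsv
frailvar summarize results.tsv --out periods.tsv
```

## Analysis scripts

`analysis/01_generate_cohorts.py` … `04_summarize_periods.py` run the full
synthetic study — twenty cohorts, four starting ages each, fitted,
decomposed and averaged within historical periods — writing TSV tables
under `results/`. Each script prints what it found.

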