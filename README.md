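# triadmix

Trivariate causal mixture modelling of polygenic overlap from GWAS summary
statistics.

## The problem

Complex traits are highly polygenic, and most trait-influencing variants
affect more than one phenotype. For a *pair* of phenotypes, causal mixture
models can estimate how many variants influence both, regardless of effect
direction. For *three* phenotypes — the setting relevant to multimorbidity,
where chronic diseases co-occur — pairwise analyses cannot pin down the
pattern: the same three pairwise overlaps are compatible with a whole range
of triple overlaps. `triadmix` fits the trivariate model directly and
reports the seven disjoint Euler components of the overlap, alongside the
maximum-entropy "naive" pattern implied by the pairwise estimates alone.

## The model

The direct (per-allele, standardized) effects of variant *j* on three
phenotypes follow a zero-mean mixture of eight components: a null component
with proportion π₀ and one component per non-empty subset *S* ⊆ {1,2,3}
with proportion π_S and covariance Σ_S built from per-trait effect-size SDs
σ₁, σ₂, σ₃ and within-component correlations ρ₁₂, ρ₁₃, ρ₂₃. The observed
z-scores are LD-weighted sums over the variant's neighborhood plus
correlated residual noise:

    z_ij = Σ_k √h_k · r_jk · √N_ij · β_ik + ε_j,   ε ~ N(0, Σ₀)

with h_k the heterozygosity 2f(1−f), r_jk the allelic correlation, N_ij the
GWAS sample size and Σ₀ parameterized by residual SDs σ₀ᵢ and correlations
ρ₀ᵢⱼ — nineteen parameters in total. The likelihood of each tag variant's z
vector is evaluated by numerically inverting the model's characteristic
function (trapezoidal rule on a fixed grid), and maximized stepwise:

1. **univariate** — (πᵢᵘ, σᵢ, σ₀ᵢ) per trait;
2. **bivariate** — (πᵢⱼᵇ, ρᵢⱼ, ρ₀ᵢⱼ) per pair, univariate fixed;
3. **trivariate** — the single triple overlap π₁₂₃ within its feasibility
   interval [max(0, πᵢⱼᵇ+πᵢₖᵇ−πᵢᵘ, …), min(πᵢⱼᵇ)].

The disjoint components follow as π_ij = πᵢⱼᵇ − π₁₂₃ and
πᵢ = πᵢᵘ − π_ij − π_ik − π₁₂₃; the naive baseline picks the π₁₂₃ in the same
interval that maximizes the entropy of the union-normalized seven-component
distribution.

## Worked example

Simulate the "ring" scenario (pairwise overlap only, no triple overlap;
π = 0.002, h² = 0.4 per trait) and fit it:

```python
import numpy as np
from triadmix import ScenarioSpec, simulate_scenario, TriadMixtureModel, Config

spec = ScenarioSpec.ring(n_variants=100_000, n_traits_N=(25_000,) * 3)
sim = simulate_scenario(spec, seed=201)
model = TriadMixtureModel.from_simulation(
    sim, Config(n_random=20_000, n_random_bivariate=6_000,
                n_random_trivariate=3_000))
ens = model.fit_ensemble(seeds=[1, 2, 3])
print(ens.representative.summary())
```

prints:

```
Trivariate causal mixture model — stepwise ML fit
==========================================================
seed: 1    tag variants: 20000    converged: True

Univariate stage (per trait)
 trait         pi^u      sigma   sigma0         loglik
     1   2.1685e-03 8.1041e-02    0.998      -29337.02
     2   2.1261e-03 8.0111e-02    0.999      -29337.08
     3   2.2289e-03 7.5653e-02    0.994      -29255.75

Bivariate stage (per pair)
  pair         pi^b      rho     rho0         loglik
1-   2   1.2365e-03    0.262   -0.002      -35171.42
1-   3   9.1327e-04    0.253    0.033      -34964.28
2-   3   9.1710e-04   -0.058    0.004      -35130.73

Trivariate stage: pi_123 = 2.7457e-05 in [2.746e-05, 9.133e-04]

Euler components (% of union):
  1:1%  2:0%  3:12%  12:35%  13:25%  23:26%  123:1%
```

The representative run recovers the simulated architecture: univariate
polygenicities near 0.002, roughly a third of the union in each pairwise
overlap, and essentially no triple overlap (1% of the union; individual
components carry ~10% sampling noise at this problem size, visible in the
trait-3-specific region). Given the same pairwise estimates, the
maximum-entropy baseline (`ens.representative.naive_pattern`) would instead
place ~12% of the union in the triple overlap — distinguishing those two
situations is exactly what the trivariate stage adds.

A `triadmix` command-line tool exposes the same pipeline on files
(`triadmix simulate`, `triadmix fit config.json`, `triadmix naive`,
`triadmix report`); configs are JSON with the conventional analysis
defaults (MAF ≥ 0.05, INFO ≥ 0.8, |z| ≤ 32, MHC excluded, random pruning at
r² < 0.8, seeded tag-variant subsets).

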