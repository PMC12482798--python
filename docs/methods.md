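# Methods

## Model

The trivariate causal mixture model treats the direct effect vector
(β₁ⱼ, β₂ⱼ, β₃ⱼ) of each variant as a draw from an eight-component zero-mean
Gaussian mixture: a null component (proportion π₀) and one component per
non-empty trait subset S with proportion π_S and covariance Σ_S. Every
variant influencing trait *i* shares the same effect-size variance σᵢ²
(discoverability), whatever other traits it affects; correlations ρᵢⱼ act
within shared components. Observed z-scores are LD-weighted sums of
neighborhood effects scaled by √(h_k) r_jk √(N_ij), plus residual noise
ε ~ N(0, Σ₀) with per-trait SDs σ₀ᵢ (≈1 in a well-calibrated GWAS; >1 under
uncontrolled stratification) and residual correlations ρ₀ᵢⱼ (non-zero under
sample overlap). Nineteen parameters in total.

Assumptions worth keeping in mind: phenotype-influencing variants are spread
uniformly through the genome; effect sizes are independent of allele
frequency and LD; residuals are treated as independent across tag variants
(a composite-likelihood approximation — the true residual field is
LD-correlated, which leaves point estimates consistent but makes naive
likelihood-based standard errors invalid, one reason inference relies on
multi-run spread instead).

A note on marginalization: restricted to a subset of traits, components
whose restrictions coincide merge (for traits {1,2}: shared proportion
π₁₂ + π₁₂₃, trait-1-specific π₁ + π₁₃, null absorbs π₃ + π₂₃ + π₀). The
joint density of three traits does *not* exactly factor into lower-order
densities even when no component couples them, because a neighbor occupying
a trait-3-only component is thereby excluded from the others — an O(π²)
coupling, negligible at realistic polygenicities but visible at π ≳ 10⁻².

## Likelihood evaluation

The density of a tag variant's z vector is recovered from the model's
characteristic function

φ(t) = exp(−½ tᵀΣ₀t) · Π_k [π₀ + Σ_S π_S exp(−½ w_k tᵀ D_N Σ_S D_N t)],
w_k = h_k r²_jk,  D_N = diag(√N_i),

by a trapezoidal sum over a fixed uniform grid. Numerical choices:

* **Half-width** T = √(2 ln(1/τ))/σ₀ per axis, with tail tolerance
  τ = 10⁻¹³ for single-variant (oracle-grade) evaluation and 10⁻⁹ / 10⁻⁷ /
  10⁻⁵ for 1-D / 2-D / 3-D fitting (cost grows with the d-th power of grid
  size; the truncation deficit is smooth in the parameters, so it barely
  moves optimizer argmaxes, and accuracy is measured by the oracle suite).
* **Step** δt = π/(z_max + m). The trapezoid sum equals the 2π/δt-periodized
  density, so the margin m controls how far the aliased images sit beyond
  the evaluation points. For single-variant evaluation m grows with a
  conservative bound on the model's z SD; for fitting, m = 4 and the
  dominant image terms — single causal neighbors with large N σ² w loads,
  whose image densities are closed-form Gaussians — are subtracted
  analytically (`_image_correction`). Without this correction a
  coarse-grid likelihood overstates the density of wide-component
  parameter regimes and the optimizer drifts toward them.
* **Banding**: variants are split at |z| = 6 and 12, each band getting its
  own grid, so a few outlying z-scores do not force a fine grid on the
  whole batch.
* **Weight binning**: within a variant, neighborhood weights within 25% of
  each other are merged into bins with integer multiplicities (arithmetic
  mean preserves the total LD load exactly). Validated against unbinned
  evaluation (≲0.03 log-likelihood units over 20k variants).
* Densities are clipped at 10⁻³⁰⁰ before logs; negative trapezoid residue
  is clipped to zero at the single-variant level.
* An exact-enumeration oracle (`pdf_exact`, feasible for neighborhoods with
  ≤ ~6 members) validates the inversion path; agreement is ~10⁻¹³ absolute
  on random draws.

## Estimation

Stepwise maximum likelihood with earlier stages frozen, mirroring how the
nineteen parameters decouple: three univariate fits (Nelder–Mead on
log-transformed (π, σ², σ₀²), two log-spaced π starts, method-of-moments σ²
start from the mean z² inflation), three bivariate fits (scaled-logistic
transform keeps πᵇ inside [0, min πᵘ]; atanh transforms for ρ, ρ₀; the ρ₀
start is the correlation of near-null z pairs), then a bounded scalar
search for π₁₂₃ (grid pre-scan plus golden-section refinement) inside the
feasibility interval. The univariate stage carries one physical constraint:
the implied SNP-heritability π σ² Σ_k h_k may not exceed 1, which keeps the
flat π/σ² ridge away from regimes the inversion grid cannot represent.

Each run selects its own variants: random LD pruning at r² < 0.8 in a
seeded visit order, then a seeded uniform subsample; one seed drives both.
The costlier 2-D and 3-D stages may run on nested seeded subsamples of the
same selection (configured via `n_random_bivariate` / `n_random_trivariate`)
— a desk-scale concession; with ample compute all stages would share the
full selection. When they do subsample, the headline scalars are re-polished
afterwards: πᵢⱼᵇ by a bounded profile search (correlations held fixed) on a
larger seeded subsample, and π₁₂₃ by a parabolic step on the full selection,
with boundary-safe support points. Because the three pairwise correlation
estimates come from separate fits, their 3×3 matrix can be jointly
indefinite; parameter assembly shrinks such a triple to the PSD boundary. Runs with different seeds are aggregated by per-component
medians; the representative run minimizes the union-normalized Euclidean
distance from the median pattern, which itself need not be feasible.

Non-convergent stages flag the run rather than aborting the ensemble.

## Synthetic data

The generator emulates the study conditions of a biobank-scale simulation:
per-trait polygenicity π = 0.002 and SNP-heritability h² = 0.4, with causal
variants assigned uniformly to the seven overlap components according to
three named scenarios — **core** (π₁=π₂=π₃=π₁₂₃, pairs zero), **ring**
(π₁₂=π₁₃=π₂₃, others zero), **equilibrium** (all seven equal). Effects are
standard-normal draws scaled so Σ_k h_k β²_ik equals h² exactly; z-scores
are built through a block-structured LD panel (AR(1)-decaying signed
correlations with random sign flips, which keeps the implied correlation
matrix PSD; cross-block r = 0; pairs below the construction floor r² = 0.01
absent, exactly as in a real panel built with an r² reporting floor).
Causal counts per component are rounded so each phenotype's causal count
matches round(π·n_variants) — on a 12,926,691-variant panel, 25,853 causal
variants per phenotype.

What the generator does **not** emulate: real genotypes and association
covariates (z-scores are drawn from the model the estimator assumes, so
recovery tests validate the estimator and its numerics, not robustness to
LD misspecification); LD-correlated residuals (an optional mode propagates
noise through the LD operator for robustness experiments, off by default);
case-control liability scales. Default σ₀ = 1, ρ₀ = 0 (independent,
well-calibrated cohorts).

### Desk-scale problem sizes

Full-scale runs in the literature use ~13M variants, N = 10⁵ and 300k tag
variants per optimization run on GPU hardware. The packaged experiments run
on one CPU core, so the scenario suite uses a 100,000-variant panel
(200 causal per trait) with 20,000 tag variants for the univariate stage;
the three-parameter bivariate searches and the π₁₂₃ bracketing run on
nested 6,000/3,000-variant subsamples, after which the headline scalars are
re-polished — πᵢⱼᵇ by a bounded profile refinement on a 12,000-variant
subsample and π₁₂₃ by a parabolic step on the full 20,000 (a single scalar
is worth the most data). Runs are aggregated by the component-wise median
of the polygenicity vector (π₁ᵘ…π₂₃ᵇ, π₁₂₃), taking medians *before* the
max() in the feasibility bound so one noisy pairwise estimate cannot
inflate the reported triple overlap; the median pattern need not be jointly
feasible and is clipped where required. The replication structure follows
the noise structure of each scenario's check. Core's triple overlap sits on
the min(πᵢⱼᵇ) upper bound, whose downward noise only averages out across
causal draws, so core uses three independent simulation replicates (one run
each). Ring's check rests on the feasibility lower bound — sums of pairwise
overlaps minus univariate totals, a contrast in which dataset-level
fluctuations largely cancel (extra shared causals raise πᵢⱼᵇ and πᵢᵘ
together) — and equilibrium's check compares the fit against a baseline
built from the same fitted inputs; both therefore use one dataset analysed
with three selection seeds, the multi-run ensemble protocol, which removes
the selection noise run medians can reach.

Residual sampling noise at this scale is dominated by coincidence counting:
a pairwise overlap of π = 10⁻³ puts only ~100 shared causal variants on a
100k panel, of which a 12k tag subsample covers roughly half, so πᵢⱼᵇ
carries an irreducible ~15% sampling error per run and the ring scenario's
π₁₂₃ lower bound — exactly zero in truth — fluctuates at the few-10⁻⁴
scale. Pattern shares should therefore be read from aggregated medians,
not individual runs. With the panel scaled down ~130×, keeping N proportional
(N ≈ 774) would leave so few causal variants that the π/σ² ridge is
unresolvable at any feasible tag count. Instead the desk default sets
N = 25,000, i.e. a per-causal-variant non-centrality N h²/n_causal = 50 —
the power regime of well-powered published GWAS (large lipid or biomarker
studies sit at N h²/n_causal ≈ 30–100), rather than the deliberately
low-powered full-scale simulation. `ScenarioSpec` without an explicit
sample size still defaults to the proportional rule
N = round(10⁵ · n_variants / 12,926,691).

## Known limitations

* Estimates at desk scale carry 10–20% sampling noise per run; patterns
  should be read from medians over replicates, as the multi-run protocol
  intends.
* The feasibility interval for π₁₂₃ is inherited from the fitted univariate
  and bivariate values; their errors propagate into (and can collapse) the
  interval.
* The Euler-diagram rendering is approximate-area (exact three-set
  area-proportional diagrams are not always realizable); the JSON pattern
  is the source of truth.
* No per-parameter standard errors; run-to-run spread is the intended
  uncertainty summary.
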