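# Methods

## Model family

All spatial priors in the package are zero-mean Gaussian fields on an
areal adjacency graph with binary symmetric neighbourhood matrix
`W` (`w_ik = 1` iff areas i and k share a border), neighbour counts
`w_i+`, degree matrix `D_w` and structure matrix `Q(c) = D_w − cW`.
The Markov members are defined through their precision matrices:

- **pCAR(c, σ)** — `Ω = σ⁻²Q(c)`.  Conditional mean coefficients
  (influence functions) `B_ik = c/w_i+`, conditional variances
  `σ²/w_i+`.  Proper for `c ∈ (c_min, c_max)`, the reciprocals of the
  extreme eigenvalues of `D_w^{-1/2} W D_w^{-1/2}`; for a connected
  graph `c_max = 1` and `c_min < 0`.
- **LCAR(c, σ)** — `Ω = σ⁻²(cQ(1) + (1−c)I)`, a precision-weighted mix
  of the intrinsic CAR and IID noise.  `B_ik = c/(1−c+cw_i+)`,
  conditional variance `σ²/(1−c+cw_i+)`.  Reduces to IID N(0, σ²) at
  c = 0; proper for `c ∈ [0, 1)`.
- **iCAR(σ)** — `Ω = σ⁻²Q(1)`, singular with rank n−1; used under the
  sum-to-zero constraint.  The covariance under that constraint equals
  `σ²Q(1)⁻` with `Q(1)⁻` the Moore–Penrose pseudo-inverse, which is
  what `covariance()` returns and what the exact sampler targets
  (sampling in the eigenbasis of `Q(1)` with the null eigenvector
  excluded).  Both proper CARs converge to the iCAR as `c → 1`.

The convolution members are defined through their covariances:

- **BYM(σ_s, σ_h)** — `ψ = ψ_s + ψ_h`, `Σ = σ_s²Q(1)⁻ + σ_h²I`.
- **MBYM(c, σ)** — `ψ = √c·φ_s + √(1−c)·φ_h` with a single scale;
  `Σ = σ²(cQ(1)⁻ + (1−c)I)`.  Fixing `σ_s = σ√c`, `σ_h = σ√(1−c)`
  makes BYM and MBYM identical laws; the reparameterization trades the
  BYM identification problem for a functional constraint on the scales.
- **Scaled variants** — the intrinsic block is divided by
  `s² = exp((1/n) Σ_i log Σ*_ii)` where `Σ* = Q(1)⁻`, i.e. the
  intrinsic component is expressed in units of its reference standard
  deviation `s` so that the geometric mean of its marginal variances is
  `1/τ = σ²` (the BYM2 convention).  This makes `σ` interpretable as an
  approximate marginal standard deviation regardless of the graph.
- **Adaptive (scaled) MBYM** — per-area weights `c_i ∈ (0,1)`,
  `ψ_i = √c_i φ_{s,i} + √(1−c_i) φ_{h,i}`, covariance
  `σ²(C^{1/2}Q(1)⁻C^{1/2} + (I−C))`.  The weight field can flag
  neighbourhood-level heterogeneity and discontinuity, at the price of
  n extra weakly identified parameters.

Dense covariance work (pseudo-inverses, correlation profiles) is capped
at `DENSE_CAP = 3000` areas with an explicit error beyond that;
everything needed by the sampler uses only the sparse structure.

## Dependence diagnostics

Marginal correlation/covariance profiles are columns of the field
covariance; partial correlations are `−Ω_ik/√(Ω_ii Ω_kk)`.  For the
singular iCAR the partial-correlation profile is computed from the
precision directly and flagged `constrained` (the precision is well
defined even though the covariance is rank n−1).  Profiles are grouped
by neighbour order = breadth-first graph distance, not geographic
distance.  The qualitative facts worth knowing (and asserted in the
tests on fixtures): correlations decay with neighbour order for the
proper CARs; the intrinsic CAR and the convolution models imply small
negative correlations with distant areas; MBYM partial correlations
are positive at first order and can turn negative at high order.

## Posterior computation

The sampler is an adaptive single-site random-walk
Metropolis-within-Gibbs.  Design points:

- **Site updates in colour blocks.**  The areas are partitioned by a
  greedy graph colouring so that no two neighbours share a colour;
  sites of one colour have conditionally independent full conditionals
  and are proposed/accepted simultaneously with vectorized arithmetic.
  This is statistically identical to a site-by-site sweep.  For
  convolution models the intrinsic component `φ_s` and the IID
  component `φ_h` are updated separately (the IID component needs no
  colouring).
- **Step-size adaptation.**  Per-site proposal standard deviations are
  adapted in batches of 50 sweeps toward a 0.44 acceptance rate
  (Roberts–Rosenthal schedule) and frozen at the end of burn-in, so the
  retained chains come from a fixed transition kernel.
- **Spatial parameter c.**  Random walk on logit(c) under a Beta(a, b)
  prior (default Beta(1,1)).  For pCAR and LCAR the prior
  log-determinants use precomputed eigenvalues:
  `log|Q(c)| = Σ log w_i+ + Σ log(1 − c α_j)` with `α_j` the
  eigenvalues of `D_w^{-1/2}WD_w^{-1/2}`, and
  `log|cQ(1) + (1−c)I| = Σ log(cλ_j + 1 − c)` with `λ_j` the Laplacian
  eigenvalues — each c proposal costs O(n), not a determinant.  For the
  (M)BYM family c enters only through the likelihood.  Adaptive models
  update all `c_i` simultaneously (independent likelihood terms).
- **Scales.**  Random walk on log σ with the appropriate rank
  (n−1 for intrinsic blocks, 2n−1 for the shared MBYM scale) under
  Uniform(0, 10) by default (half-normal available).  The uniform bound
  is deliberately generous for log-risk scales, which rarely exceed 1
  in practice; the informative-prior route to BYM identification is to
  tighten this bound.
- **Level identification.**  The likelihood cannot separate μ from a
  constant shift of an intrinsic field.  Models with a constant-weight
  intrinsic component are recentred every sweep: the component mean is
  subtracted and added to μ (likelihood-invariant; prior-invariant on
  the flat direction).  For adaptive models the shift enters the
  likelihood through the varying weights, so an exact transfer is
  impossible; instead a symmetric Metropolis translation move along the
  flat direction is used, which preserves the posterior exactly.
- **μ, β.**  Gaussian random walks with N(0, 100²) priors; the
  likelihood change for an intercept or coefficient shift has a closed
  O(n) form.

Defaults are 2 chains × 15,000 iterations with 5,000 burn-in, all
overridable; with the vectorized updates a 100-area model runs at
roughly 2,500 sweeps per second on one core.  Same seed, same
configuration → bit-identical chains (one spawned substream per chain).
A non-finite Poisson mean aborts with a state dump.

Correctness of the sampler is checked three independent ways in the
test suite: prior recovery with the likelihood disabled (chains must
reproduce the analytic field moments and the Beta prior on c),
posterior concentration (y = E with enormous E pins every relative
risk at 1), and agreement of BYM and MBYM risk posteriors when their
covariances are matched and fixed.

## Model comparison

DIC and WAIC are computed from the conditional Poisson likelihood of
the λ chains.  The effective-parameter count is
`pD = Dbar − D(λ̄)` with the plug-in at the posterior mean of λ; since
λ is common to every parameterization of the same fitted means, this
pD (and hence DIC) is invariant to reparameterization — BYM and MBYM
chains encoding identical λ draws score identically.  A plug-in at the
posterior mean of log λ is exposed as an option.  The deviance keeps
the `log(y_i!)` constant so absolute scores are meaningful.  WAIC uses
the variance-based penalty (pointwise sample variance of the log
predictive density, divisor T−1).  Preference rates count strict
inequalities; ties are logged and counted as non-preference.

## Synthetic data and what passing tests show

The generator draws ψ exactly from the requested field (components
retained for convolution truths), applies `γ = exp(μ + Xβ + ψ)` and
draws `y_i ~ Poisson(E_i γ_i)`.  Expected-count regimes are uniform
over areas: extremely_small (E=2), small (E=5), modest (E=50), large
(E=1000), spanning extremely rare to common diseases; per-replicate
streams are derived from (scenario seed, replicate index) so any
replicate can be regenerated alone.  Regular rook/queen lattices stand
in for real county maps.  What this does *not* emulate: the irregular
degree distributions of real maps (real county graphs mix w_i+ from 1
to 10+), population-driven heterogeneity in E, covariate confounding,
and data anomalies (zero-population areas, boundary effects).  Passing
simulation tests therefore demonstrate correctness of the machinery
and calibration under the stated conditions, not performance claims
for any particular real map.

The headline acceptance run uses a small-count regime (E=5, 8×8
lattice, LCAR(0.8, 0.4) truth, 10 replicates, five fitted priors,
4,000 retained draws per fit) — sizes chosen so the full five-prior
sweep completes in about two minutes on one core while pooling 640
(area, replicate) intervals per prior, enough to estimate coverage to
about ±1 percentage point.

## Numerical choices and edge cases

- Eigendecompositions use symmetric routines (`eigh`/`pinvh`);
  the intrinsic null space is detected at `1e-10` relative tolerance.
- `c = 0` and `c = 1` are admitted as the IID and intrinsic limits of
  LCAR/MBYM (the `c = 1` proper-CAR case falls back to the intrinsic
  sampler/pseudo-inverse).
- Islands (`w_i+ = 0`) are rejected for any model containing an
  intrinsic or pCAR component (conditional variance `σ²/w_i+`
  undefined) and accepted for LCAR/IID components.
- The scaling constant is only defined on a connected graph (the
  pseudo-inverse would mix components otherwise); disconnected input is
  rejected rather than silently per-component.
- Zero counts are fully supported; saturated-risk comparisons in tests
  skip `y_i = 0` areas.
- GeoBUGS `num`/`adj` input is symmetrized with a logged warning when
  the listing is asymmetric; self-loops, duplicate edges and
  out-of-range indices are errors with line context.
- Point estimates default to posterior medians (with means as an
  option); intervals are equal-tailed 2.5/97.5 percentiles.

## Known limitations

- Single-disease mapping only: no multivariate/shared-component models.
- Binary adjacency only: no distance- or covariate-weighted W.
- Random-walk MCMC mixes slowly for strongly identified, highly
  correlated posteriors compared to gradient-based samplers; the
  spatial parameter c in particular carries wide posteriors on small
  maps regardless of sampler, because a single field realization is
  weakly informative about it.
- The adaptive MBYM weights are weakly identified in univariate
  mapping; treat their posteriors as exploratory flags, not estimates.
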