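# Methods

## Model

The package simulates and estimates the evolution of linear reaction
norms for p traits responding to q environmental cues. Individual
phenotypes are

    y_ji = ā_j + a'_ji + v_ji + Σ_k (b̄_jk + b'_jk,i + η_jk,i) u_k ,

with mean intercepts ā (trait units), mean slopes B̄ (trait units per cue
unit), additive deviations (a', b') drawn with covariance G across the
p(1+q) effects and relationship matrix A across individuals, and iid
nonadditive deviations v, η with variances σ²_v (per trait) and σ²_η (per
trait × cue). Cues are deviations from a reference environment fixed at
zero, so no code ever re-centers them. The phenotypic covariance is
derived, never stored: P = G inflated on the diagonal by the nonadditive
variances. Effect columns are ordered trait-major —
[a'_1..a'_p, b'_11..b'_1q, ..., b'_pq] — everywhere in the package.

Fitness is stabilizing and Gaussian: the number of descendants is
W_i = round(W_max · exp(−‖y_i − θ_t‖² / 2ω²)), rounded half away from
zero, an integer in [0, W_max]; relative fitness w_i = W_i / W̄ has mean
exactly 1. The population size is held constant by construction: each
generation a fresh cohort of n individuals is drawn, and fitness enters
only through the selection covariances. Inheritance is carried entirely
by the mean parameters (ā, B̄); individual deviations are redrawn each
generation from the fixed G, A and nonadditive variances. This is the
state-space reading of the evolutionary model: the mean is the state,
the within-generation distribution is stationary around it.

### Estimation

At each parent generation the phenotypes follow the linear mixed model

    y_t = X ȳ_t + (Z(u_t) ⊗ I_n) x_t + e_t ,

with fixed effects the p mean traits (X = I_p ⊗ 1_n), random effects the
stacked additive deviations (covariance G ⊗ A), and diagonal residual
covariance R(u_t) ⊗ I_n with r_j = σ²_vj + Σ_k u_k² σ²_ηjk. Both Z and R
depend on the current cues — the "dynamical" part. Henderson's
mixed-model equations give the BLUP estimates (ŷ̄, x̂); R being diagonal
and per-trait makes every block of the system a small matrix Kronecker
I_n, which the solver exploits (below).

### Updating

Four per-generation update rules for the mean parameters:

- **robertson** — Δz̄_m = cov(w, x̂ column m): Robertson's secondary
  theorem applied to the estimated random effects. The only rule
  computable from observable data (phenotypes, fitness, cues, A).
- **blup_closed** — the closed form
  G (ZᵀR⁻¹Z G + I)⁻¹ ZᵀR⁻¹ cov(w, y), algebraically equal to the
  Robertson rule when A = I, for any n ≥ 2.
- **grad** — the selection-gradient form G Zᵀ P_yy⁻¹ cov(w, y) with
  P_yy = Paa + Gab U + (Gab U)ᵀ + Uᵀ Pbb U. Equal to the BLUP rules when
  A = I; under relatedness it ignores A and is therefore the wrong-model
  comparator. The cross term is symmetrized so P_yy is symmetric for
  nonzero Gab (inert in the default system, where Gab = 0); the identity
  with blup_closed is the numerical check on that reading.
- **breeder** — the multivariate breeder's equation G P⁻¹ cov(w, ·)
  applied to the *true* individual intercepts and slopes. Simulation-only
  (those are unobservable); agrees with GRAD only as n → ∞.

A single population-covariance implementation (1/n normalization, the
Price-equation convention over the realized population) is used by every
rule; the closed-form identities hold under either convention provided it
is consistent, and routing all rules through one function enforces that.

With overlapping generations only a fraction f_t ∈ (0, 1] of each
generation are new offspring and every increment is multiplied by f_t.
Updates are applied once per generation, after fitness is realized and
before the next cohort is drawn; the Price-equation transmission term is
assumed zero (estimated breeding values pass to descendants unchanged in
fitness-weighted expectation).

## Environment generator

Cue means follow linear ramps starting at generation `ramp_start`
(default 10 of 60): mean cue = slope · (t − ramp_start) for t beyond the
start, zero before. The mean optimum is a linear map of the mean cue
(default diag(−2, −2)). Around the means, the q cues and p optima
fluctuate as jointly normal white noise with a single (q+p)×(q+p)
covariance; the default values are cue variances 0.5 and 0.1875, optimum
variances 2 and 1, cue-cue covariance 0.25 and within-channel cue-optimum
covariances −0.25 and −0.09375, with unlisted cross-covariances set to 0.
The negative cue-optimum covariance is what gives plasticity its value: a
warm year moves the optimum down, and a negative slope moves the
phenotype with it. The ramp slopes default to 0.05 and 0.015 per
generation (mean rises of ≈2.5 and ≈0.75 cue units over the 50
post-onset generations). Noise is white by construction — no
autocorrelation and no within-generation heterogeneity among individuals.

The initial means are the stationary optimum: zero intercepts and slopes
b̄_jk = cov(u_k, θ_j)/var(u_k) (−0.5 on both active channels by default,
the minimizer of E(y − θ)² in the stationary environment; zero where a
cue and an optimum are uncorrelated or the cue is constant).

## Relatedness

Two built-in structures: A = I (unrelated) and the banded high-relatedness
matrix (1 diagonal, 1/2 first off-diagonals, 1/4 elsewhere); arbitrary
matrices load from headerless CSV. A_M is the *symmetric* PSD square root
from an eigendecomposition with negative eigenvalues clipped at zero
(A_M A_M = A; a Cholesky factor would satisfy only L Lᵀ = A). Additive
effects are drawn as z = A_M z0 with z0 ~ N(0, G) and then mean-centered;
centering plus the A_M transform leaves the realized column variances at
(tr A − 1ᵀA1/n)/n of nominal — 73.75% analytically for the banded matrix
at n = 100, the ≈75% reduction quoted with the banded-relatedness runs.
Nonadditive effects are neither relatedness-correlated nor centered.

## Numerical choices

- **Degenerate effects.** A structurally absent parameter (zero additive
  and nonadditive variance, e.g. the default system's cross-slopes b12,
  b21) makes the full G singular. The solver drops effect columns with
  zero additive variance and re-embeds zeros in x̂; the breeder rule drops
  components with zero phenotypic variance before inverting P. This is
  equivalent to writing the reduced model directly.
- **Solver paths.** For A = I the mixed-model equations decouple: the
  fixed effects are the trait means and each individual solves the same
  k×k system S = ZᵀR⁻¹Z + G⁻¹ against its centered record; this path is
  O(n k²) and makes the 100-replicate drift study and the n = 10⁵
  shrinkage check cheap. For general A a dense symmetric Henderson system
  of size p + kn is formed (with G̃⁻¹ = G⁻¹ ⊗ A⁻¹; pseudo-inverse with a
  warning if A is singular) and solved directly — robust at the study
  scale of ≲10³ unknowns. The two paths agree to machine precision and
  are both checked against an independent GLS/conditional-expectation
  oracle (x̂ = G̃Z̃ᵀV⁻¹(y − Xŷ̄), V = Z̃G̃Z̃ᵀ + R̃) in the tests.
- **Symmetry/PSD checks** use relative tolerance 1e−8; residual variances
  must be strictly positive (otherwise the model is unidentifiable and an
  error says so).
- **Rounding** of fitness is half away from zero.
- **Seeding.** A run's seed feeds a `SeedSequence`; the environment and
  the cohort stream get independent children, and replicate experiments
  spawn one child per replicate. Identical seeds give bit-identical runs.
- **Shared draws.** Within a run all update rules see the same
  environment and the same per-generation draws of (a', b', v, η), so
  method comparisons are paired (variance-reduced); phenotypes and
  fitness still differ across methods through their evolving means. An
  independent-draws mode is available via `shared_draws=False`.

## Simulation studies and their scales

- **Generation loop**: T = 60, n = 100 by default; all rules, any A.
- **Overlap study**: the same run at f_t = 1 and 0.5 with shared
  randomness; reports time-averaged mean fitness over the ramp period.
  Slower tracking under f_t = 0.5 appears as a larger average distance to
  the optimum and lower mean fitness.
- **Drift study**: 100 replicates × 60 generations × n = 100 with ramps
  disabled; reports the across-replicate mean and SD of the total change
  in ā_1. "SD" here is the across-replicate standard deviation of the
  change (not divided by √reps). Replicates re-randomize everything,
  including the optimum noise (cues and optima are a joint draw). The
  package measures an SD of ≈0.13 under the default conditions.
- **Environmental drift diagnostic**: 100 replicates of the stationary
  cue-1 series, each summarized by the endpoint change of an OLS line fit
  against generation index; the analytic SD is
  (T−1)·√(var_u / Σ(t−t̄)²) ≈ 0.311 at T = 60, var = 0.5. Most of the
  loop's drift is attributable to this apparent environmental trend
  rather than to genetic sampling: the loop's drift SD is roughly the
  diagnostic SD scaled by the evolved intercept response, and population
  size barely affects it above n ≈ 10.

## What the generator does and does not emulate

The synthetic environment reproduces the *structure* the method needs —
ramped means, jointly fluctuating cues and optima, white noise — not any
real climate series. Cohorts are ideal mixed-model data: exactly linear
norms, exactly normal effects, known constant G and P, mid-parent
(asexual) inheritance of the mean, constant n. Passing tests therefore
demonstrate internal correctness of the estimator and updating rules
under the model's own assumptions; they say nothing about robustness to
nonlinear norms, non-normal effects, estimated (rather than known)
variance components, autocorrelated environments, or real pedigrees.
Parameter identification from data (prediction-error methods, REML) is
out of scope — with plastic traits, single-generation REML is
indeterminate because each residual variance confounds several
nonadditive variances.

## Known limitations

- Dense solver: general-A cohorts beyond a few hundred individuals become
  slow/memory-heavy; no sparse or iterative path is provided.
- The relationship matrix is constant and user-supplied; no pedigree
  construction.
- Fitness is the rounded-Gaussian descendant count only; no alternative
  fitness models.
- Extinction (all fitness zero) aborts a run with a diagnostic rather
  than being modeled.
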