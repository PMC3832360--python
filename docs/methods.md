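# Methods

## Pedigrees and relationships

Pedigrees are collections of independent families (cross-family parent
links are rejected: each family is a self-contained relationship graph).
The expected additive relationship 2Φ is computed by the classical kinship
recursion in parental (topological) order,

    φ(i,j) = ½[φ(fa_i, j) + φ(mo_i, j)],    φ(i,i) = ½[1 + φ(fa_i, mo_i)],

with missing-parent terms contributing zero, so half-sib links, single
known parents and inbreeding loops are all handled. The diagonal is 1 + f
(f the inbreeding coefficient). Cross-family entries are zero without
computation and the matrix is block positive semi-definite by construction.
Missing parents may be coded `0`, empty, or `NA`; unknown sex is accepted
(a parent of unknown sex is permitted in either slot). Individuals
phenotyped but absent from the pedigree are a hard error — silently
dropping rows would corrupt the family-block likelihood.

Two independent cross-checks guard the recursion in the test suite: exact
enumeration of all Mendelian transmission vectors (feasible for families up
to ~16 transmissions) and Monte-Carlo gene dropping (founders carry unique
allele labels; 2Φ is estimated as twice the mean of the four
allele-matching indicators, SE ∝ 1/√n_drops).

## Activity diaries and TDEE

A diary is 3 days × 96 quarter-hour periods, each coded 1–9 in increasing
intensity. TDEE (kcal/day) = body weight (kg) × Σ_c n_c·cost_c / 3, where
n_c counts periods of category c over the 3 days and cost_c is the
per-category energy cost in kcal/kg/15 min. The default cost table
(0.26 … 2.0) comes from the Bouchard 3-day activity-record literature; it
is a configurable external constant, not a study estimate. Diaries with the
wrong period count or out-of-range codes are rejected, never repaired.
Precomputed TDEE columns bypass the diary path entirely.

Before entering the variance functions, TDEE is standardized to mean 0 and
SD 1 (sample SD, n−1). This is a pure reparameterization — the likelihood
is invariant under q → q + c with α → α − γc — but exp(γ·q) with raw
kcal/day values overflows, so the standardized scale is the default and
slope/decay parameters are additionally reported per 1000 kcal/day.

## Covariate adjustment and normalization

Each trait is adjusted by OLS on {1, sex, age, age², age×sex, age²×sex}
(terms configurable), pooled across generations, with listwise deletion per
trait and excluded ids logged. Residuals are mapped to normal scores by the
rank-based inverse normal transformation with Blom fractions,
Probit((r − 3/8)/(n + 1/4)); ties get average ranks; the offset is
configurable (0, 3/8, or 1/2). The two-stage residual-then-transform
approach means the variance-components fits carry only a grand mean.

## Maximum likelihood

Both models factorize over families; families are grouped by size and the
covariance blocks, Cholesky factorizations and quadratic forms are batched
through numpy, so a full 958-subject fit takes well under a second.

- Polygenic: parameters (μ, log σ²e, σ²g) with σ²g ∈ [0, ∞) so the
  boundary is reachable; L-BFGS-B from heritability starts {0.1, 0.4, 0.7};
  best likelihood kept. se(h²) by the delta method on the inverse observed
  information (numerical Hessian in natural parameters); reported as NaN at
  the σ²g = 0 boundary where the Wald approximation fails. The reported
  95% CI is Wald h² ± 1.96·SE truncated to [0, 1].
- GxEE: parameters (μ, αg, γg, λ, αe, γe) with λ ∈ [0, ∞); constrained
  fits freeze any of {γg, γe, λ} at zero. Starts combine a moment-based
  intercept pair with a grid γg ∈ {−0.5, 0, 0.5} × λ ∈ {0, 0.1, 1}; the
  most promising grid points are refined, plus (when available) a start at
  the polygenic solution, which guarantees the full model never falls below
  its nested polygenic optimum. Multistart audits showed the refined
  optimum is the global one to ~1e-10 in log-likelihood.
- Convergence: L-BFGS-B with ftol 1e-12, gtol 1e-8. Cholesky failure or
  overflowing exponents return −∞ and are stepped around by the optimizer;
  the GxEE covariance is positive definite for any valid parameters because
  exp(−λ|Δq|) is a positive-definite kernel and the Schur product with the
  PSD relationship block plus a positive diagonal stays PD.

Likelihood-ratio statistics are T = 2·ΔLnL, clamped at zero for roundoff
below 1e-6 and raised as optimizer failures beyond that. Null
distributions: γg = 0 is an interior hypothesis (χ²₁); λ = 0 and h² = 0 sit
on a boundary (½χ²₀ + ½χ²₁); the full-vs-polygenic contrast frees three
parameters with one on the boundary (½χ²₂ + ½χ²₃). The last form is
validated against the published table's printed p-values (T = 0.408 →
p = 0.877; T = 12.601 → p = 0.004) rather than taken on authority. No
multiple-testing correction is applied across traits.

## Synthetic data generator

The generator emulates a 294-nuclear-family study with 958 phenotyped
members. Both parents always appear in the pedigree (they carry the sibling
relationship structure even when unphenotyped); participation quotas pick
exactly 180 phenotyped fathers, 253 mothers, 265 sons and 260 daughters,
with a repair pass guaranteeing every family keeps at least two phenotyped
members (mean family size 3.3). A stochastic thinning mode (independent
per-role participation probabilities, configurable family-size
distribution) is available for designs of other sizes, and
`scale_role_counts` rescales the reference profile.

TDEE is drawn per role from normals with means/SDs (kcal/day) of
3561.79 ± 962.71 (fathers), 2788.37 ± 527.58 (mothers), 2280.57 ± 774.43
(sons) and 2024.85 ± 568.43 (daughters), truncated below at 500 kcal/day to
exclude nonphysical draws. Parent ages are normal (45.36 ± 5.17 /
43.49 ± 4.47 years), offspring ages uniform on [10, 18]; body weights are
role-conditional normals (typical adult/adolescent values, needed only for
diary round-trips). Optional diaries are built by a greedy integer
construction whose category counts reproduce the drawn TDEE to within one
15-minute period's cost.

Trait scores are drawn per family from the same covariance assembly code
path the likelihood uses (`gxee` truth, or `polygenic` truth as its exact
γ = 0, λ = 0 special case; default heritabilities 0.21–0.59 across the six
trait labels), plus configurable age/sex mean effects so the covariate
adjustment has real work to do. All generators are pure functions of
(config, seed): identical seeds give byte-identical files.

What the generator does **not** emulate: assortative mating, shared
household environment, measurement error in the diaries, trait-specific
raw-scale distributions (scores are generated on the normalized scale), or
missingness mechanisms beyond the participation quotas. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to those real-data features.

## Problem sizes in the test and acceptance runs

Simulation-backed checks are run at sizes chosen to keep the default suite
quick while leaving Monte-Carlo error well inside the asserted tolerances:
parameter recovery at 500 four-member families × 50 replicates (each mean
within 3 MC SEs of truth), type-I error calibration at 100 families × 500
replicates against the exact binomial 95% acceptance region, nesting
identities on 20 datasets, oracle equivalences on 100 random cases, and
gene dropping at 200,000 drops. `scripts/acceptance.py` uses 20-replicate
recovery runs and 200 calibration replicates.

## Known limitations

- Only additive relationship matrices: no dominance or X-linked components,
  no marker-based (realized) kinship, no household variance component.
- The environmental correlation across exposure levels is fixed at
  identity; only the genetic correlation gets the exponential-decay
  function. γe is always fitted and reported in the full model.
- TDEE does not enter the mean model by default (means are adjusted for
  age/sex only); the design matrix for adjustment is configurable if a
  sensitivity analysis needs it.
- Wald intervals for h² are poor near the boundary; the boundary LRT
  p-value is the preferred inference there.
- Under a no-interaction truth the single-replicate sampling SD of γ̂g at
  300 four-member families is ≈ 0.25 (the estimates are unbiased but not
  tightly concentrated); detecting slopes of |γg| ≈ 0.5 reliably needs
  several hundred families, consistent with the power checks in the suite.
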