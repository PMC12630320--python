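# Methods

## Model class and notation

A matched-comparison model consists of `b` independent blocks of `m`
outcomes. Within block `i` the outcomes are independent with densities known
up to a shared interest parameter `ψ` (scalar or, for triplets, a pair) and
a block-specific nuisance parameter `λᵢ`; some models add a parameter shared
across blocks (the Weibull shape `α`, the log-logistic shape `β`). The
nuisance parameters are treated as *fixed constants*, not draws from a
mixing distribution: all asymptotic statements in the experiments module are
along sequences of fixed `λ`-grids, which are recorded in the study output.
The regression models (`exp_reg`, `loglogistic_reg`) are the `m = 1` case
with covariates: the block structure is replaced by pairing each unit with a
reference unit, and one global scale `λ` plays the nuisance role.

## The factorisation criterion and the characteristic PDE

A statistic `s` has a nuisance-free law exactly when its Laplace transform
`E[exp(−z·s(Y))]` is constant in `λ`, identically in `z` and `ψ`. The
operational route is:

1. **Factorised form.** Verify that the block density can be written
   `κ · ∏ⱼ wⱼ′(yⱼ) · g(w(y); ψ)` with bijective per-outcome maps `wⱼ(yⱼ; ψ, λ)`
   and `λ`-free `g`. `check_factorisation_form` attempts a full symbolic
   simplification of the ratio density/candidate; when that fails it reports
   the maximum relative deviation from 1 on a grid over outcomes and
   nuisance values (log-spaced over the bulk of the support for positive
   outcomes, linear otherwise) and returns a negative verdict. Monotonicity
   of each map on the support is checked numerically; `κ ≤ 0` is rejected.
2. **Characteristic field.** In the transformed variables the criterion
   becomes `∂s/∂λ = 0` along the flow, i.e. the PDE `Σⱼ aⱼ ∂s/∂yⱼ = 0` with
   `aⱼ = ∂yⱼ(wⱼ; ψ, λ)/∂λ`. The coefficients are computed by implicit
   differentiation, `aⱼ = −(∂wⱼ/∂λ)/(∂wⱼ/∂yⱼ)`, which needs no closed-form
   inverse map. (For the mean-shift pair model this yields
   `a = −t/{λ(1−λψ)}`; displayed versions of this coefficient elsewhere drop
   the minus sign, which is immaterial: only the direction field `b/a`
   matters.)
3. **First integrals.** For `m = 2` the PDE is solved by one characteristic
   ODE `dc/dt = b/a`, handed to sympy's ODE solver; the integration constant
   solved back out of the solution is the first integral. For `m > 2` each
   outcome is paired with the last one, giving `m − 1` integrals completed
   by `r = y_m`; joint bijectivity is certified by a non-vanishing Jacobian
   on a probe grid. If the symbolic solve fails, characteristics are traced
   numerically (`solve_ivp`, rtol 1e−9) from the query point back to a
   reference abscissa, and the crossing level *is* the first integral —
   flagged `method="numeric"` in the output.

### Canonical representative

Solutions come in equivalence classes `{s^k : k ≠ 0}` (plus multiplicative
and additive constants). The canonicaliser picks `k = 1` by dividing
rational exponents by their gcd, strips constants and parameter-only
factors, and orients the representative to be increasing in the first
outcome symbol where it is monotone (probed numerically at interior points).
This gives `t/c` for the hazard-ratio pair and `t − c` for the Cauchy pair;
for the mean-shift pair it gives `t^β/c`, the `k = −1` member of the class
conventionally written `c/t^β`. The canonicaliser is idempotent and
class-collapsing, both under test.

### Two nuisance directions

With one statistic and two outcomes, eliminating two nuisance parameters
simultaneously requires the two characteristic direction fields to coincide
everywhere; `joint_solvability` implements this as the vanishing of the
determinant `a₁b₂ − a₂b₁`. The theory asserts non-existence for the Weibull
pair without giving a criterion; the determinant test is this module's
formalisation and is valid for two outcomes only (no Frobenius-type analysis
for larger systems is attempted). When no common solution exists the report
recommends eliminating the per-block nuisance, since each block introduces a
fresh copy of it.

### Perturbed factorisations

When exact factorisation fails, the right-hand side of the criterion is
allowed to be a slowly varying function `h(λ)`, operationalised — since no
definition of "slowly varying" is available — as its quadratic expansion
`κ + ε₁(λ−λ₀) + ε₂(λ−λ₀)²` around a base point. Along the characteristic
flow parameterised by `λ`, the perturbed equation integrates directly: the
returned statistic is the homogeneous first integral plus the antiderivative
of `h` vanishing at `λ₀`. The zero-perturbation limit returns the
homogeneous solution exactly (asserted in code). The expansion constant `κ`
here is an unrelated quantity to the normalising constant `κ` of the
factorised form and to the Gram–Schmidt index `κ`; the three live in three
distinct types.

### Taylor simplification and plug-in

`taylor_simplify` expands a parameter-dependent statistic to leading order
in the product `ψλ` around 0 (the relevant small quantity for the mean-shift
pair, whose domain is `|ψλ| < 1`), producing `c/t` up to class. The plug-in
variant replaces a parameter-dependent exponent on an outcome symbol with
the crude first-moment estimate `t/c` (for the mean-shift pair,
`E(T)/E(C) = β` exactly), yielding the class of `c/t^{t/c}`.

## Verification

No Bromwich inversion is performed: the transform is used only as a
criterion. `lambda_independence_check` combines

- a central finite-difference derivative of `E[exp(−z s)]` in `λ` (step
  `1e−4·λ`, tolerance `1e−5`) over a `(z, ψ, λ)` grid of adaptive 2-D
  quadratures (absolute error below `1e−7` enforced), and
- pairwise two-sample KS tests at the 1% level between simulated statistic
  samples across `λ` values (default 20 000 draws per value, fixed seed).

The KS leg is decisive when quadrature fails — by design for statistics
whose transform diverges (e.g. `t − c` against Cauchy tails) and for ratio
laws without moments. `marginal_density_check` certifies closed-form
statistic densities by one-sample KS against a dense-grid numeric CDF of the
candidate (trapezoidal on ~4000 nodes spanning the sample, tail mass by
quadrature), after confirming the candidate integrates to one. The "depends
weakly on λ" notion has no prescribed tolerance; the report quantifies
dependence via the KS table and the pass threshold (α = 0.01) is a surfaced
design choice.

## Estimators

- **Marginal MLE (ratio statistics).** Solves
  `(2/b) Σ ψ²sᵢ/(1+ψ²sᵢ) = 1` by Brent root-finding on `log ψ` with
  automatic bracket expansion (the left side is monotone from 0 to 2, so the
  root is unique). The standard error is `{−ℓ″(ψ̂)}^{−1/2}` with the second
  derivative by central differences (`h = 1e−5·ψ̂`), so the same code serves
  numerically specified densities. The large-`b` limit of the score's mean
  is available in closed form (`limit_function`); its removable singularity
  at `κ = ψ` (value 1/2) is handled by an analytically cancelled series
  switch inside `|κ/ψ − 1| < 1e−4`.
- **Joint MLE (hazard-ratio pairs).** Profiling `λ̂ᵢ = 2/(tᵢψ + cᵢ/ψ)`
  reduces the likelihood equation to `Σ (cᵢ/ψ − tᵢψ)/(cᵢ/ψ + tᵢψ) = 0`.
  Each term equals `1 − 2ψ²sᵢ/(1+ψ²sᵢ)` with `sᵢ = tᵢ/cᵢ`, so this equation
  is *algebraically identical* to the marginal one: the two point estimators
  coincide at every `b`, not merely asymptotically. What differs is
  calibration: the joint fit's curvature-based variance is unreliable under
  fixed-nuisance asymptotics, so no analytic standard error is attached to
  it.
- **Inconsistent profile fits.** Normal pairs: `σ̂² = (1/4b) Σ(yᵢ₁−yᵢ₂)²`,
  the joint MLE with per-pair means profiled, with probability limit
  `σ²/2`. Binary pairs: per-pair profiling gives `λ̂ᵢ = −ψ/2` on discordant
  pairs and `±∞` on concordant pairs (whose profiled contribution is then
  `ψ`-free and is dropped); the profile objective is maximised at
  `ψ̂ = 2·log(n₁₀/n₀₁)`, twice the conditional estimator `log(n₁₀/n₀₁)`.
  Both closed forms are cross-checked in the tests against brute-force joint
  maximisation over `(ψ, λ₁,…,λ_b)`. Zero discordant counts of either type
  flag an infinite estimate with no interval.
- **Moment estimator (mean-shift pairs).** `ψ̂ = (1/2b) Σ(cᵢ−tᵢ)` with the
  composite variance estimator
  `σ̂² = (1/2b²) Σ tᵢcᵢ + ψ̂²/b`, consistent for
  `ψ²/(2b) + (1/2b²) Σ λᵢ^{−2}` without estimating any individual `λᵢ`; the
  pivot `(ψ̂ − ψ₀)/σ̂` is exposed as a callable for interval inversion.
- **Confidence-set scan.** For each trial `ψ₀`, statistics `s(t, c; ψ₀)` are
  standardised by the probability integral transform under their null CDF
  and tested for uniformity (one-sample KS); non-rejected `ψ₀` form the set.
  The test, level and standardisation are unprescribed upstream; PIT + KS at
  the stated level is this package's choice, surfaced as arguments. A
  pathology flag is raised when the retained set touches the grid boundary
  or covers most of the grid — the signature of a statistic identifying only
  a composite such as `ψλ`, as happens for `c/t` in the mean-shift model.

## Synthetic data

`sample_blocks` draws from the exact catalog distributions via scipy
(exponential, Weibull, Cauchy, normal, Bernoulli, Fisk/log-logistic), one
deterministic generator stream per call, vectorised per arm; same seed, same
sample. Nuisance sequences may be fixed vectors, deterministic quantile
grids (the default in studies, matching the fixed-constants formulation), or
i.i.d. draws offered purely as a convenience. Default study settings follow
the stated conditions of the claims they probe: `σ² = 1`, `b = 10⁵`, 20
replicates for the normal inconsistency; `ψ = 1`, `b = 5·10⁴`, 20
replicates, standard-normal quantile `λ`-grid for the binary inconsistency;
`μᵢ` on a uniform [2, 4] grid for the moment-estimator study. The generator
emulates independence within and across blocks and exact parametric shapes;
it does not emulate censoring, covariate-dependent nuisances `λᵢ = h(xᵢᵀβ)`,
treatment-effect heterogeneity across blocks, or model misspecification — a
green verification test certifies distributional claims *under the stated
model*, nothing more.

## Numerical choices

- Quadrature: scipy adaptive (QUADPACK) with `epsabs = 1e−9` for transform
  values, `1e−10`–`1e−12` for the orthogonality and Stein integrals;
  semi-infinite ranges handled natively, truncation only inside the
  dense-grid CDF construction (tail mass re-added by quadrature).
- Root-finding: Brent on `log ψ` (interest parameters are positive wherever
  the estimators apply), bracket expanded until a sign change, `xtol 1e−13`.
- Probe grids for residuals and monotonicity: geometric over [0.05, 4] for
  positive outcomes, linear over [−2.5, 2.5] otherwise, at a fixed interior
  reference parameter point (`ψλ` well inside the unit disc for the
  mean-shift model).
- KS decisions use p-values (exact/asymptotic as scipy selects) against
  α = 0.01 rather than tabulated critical constants.

## Known limitations

- The solvability determinant covers two outcomes and two nuisance
  directions only.
- The numeric characteristic fallback fixes parameters at reference values;
  its output is a callable level function, not an expression, and carries no
  parameter-freeness analysis.
- The Gram–Schmidt and Stein constructions are certified (orthogonality,
  zero expectation, power against a wrong law) but are not used to solve the
  underlying integral equation for a statistic — no operational algorithm
  exists for that route.
- Whether the printed orthogonal partner is unit-normalised is not asserted
  anywhere; only orthogonality is, and only orthogonality is tested.
- Binary models are outside the PDE machinery (no smooth change of
  variables); they are served by the conditional analysis instead.
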