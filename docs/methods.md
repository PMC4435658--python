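# Methods

## Model

The package estimates generalized varying coefficient models for repeated
cross-sectional surveillance data.  For respondent i with binary outcome
y_i, categorical covariates and interview wave t_i ∈ {1, …, T},

    g(μ_i) = b0 + Σ_j b_j z_ij + a_0(t_i) + Σ_j x_ij a_j(t_i),

with g the logit link (a Gaussian/identity family is also supported, and
is used internally for residual fits).  Constant effects enter through
dummy coding with a declared reference level.  A *varying* categorical
term contributes one smooth a_{j,ℓ}(t) per level — the reference level
included — plus the ordinary constant dummies for the non-reference
levels, so the smooth captures how a category's effect drifts around its
average.  `varying_intercept` adds a_0(t), the common drift of the
baseline odds.

Each smooth is a P-spline: a_j(t) = Σ_l γ_jl B_l(t) with k cubic
B-spline basis functions on equally spaced knots over [1, T] (k = 55 in
the headline configuration, i.e. one basis function per wave) and an
order-2 difference penalty λ_j‖Δ²γ_j‖².  The penalty's null space is the
linear functions, so λ_j → ∞ shrinks a smooth to a straight line; the
basis is deliberately rich and the penalty does the smoothing.

Knot layout: the number of basis functions k, the spline degree p and
the closed domain [t_min, t_max] determine m = k − p equal interior
intervals, with p extension knots on each side.  Equally spaced knots
(not quantile-based) are the defining convention of P-splines.  The
right domain boundary is valid input (the last interval is closed).

## Identifiability

Fitting both a constant coefficient and a smooth for the same category is
confounded unless the smooth is centred.  Every smooth is constrained to
sum to zero over the *unique observed waves* — the same normalization the
synthetic generator applies to its varying effects, so fitted and true
decompositions are directly comparable.  The constraint is absorbed by
solving for one spline coefficient (the one with the largest basis column
sum, for conditioning), a sparse reparameterization that keeps design
matrices sparse; the penalty is transformed accordingly.

One genuine non-identifiability remains by construction: when a varying
intercept coexists with a full set of per-level smooths (or two varying
terms each carry full level sets), a common *linear* trend — centred and
penalty-free — can move between blocks without changing fit or penalty,
so the penalized normal matrix is exactly singular in that direction.
The solver detects this and pins the direction with a tiny ridge
(10⁻¹⁰ × mean diagonal, escalating only as far as needed), i.e. it
reports the minimum-norm representative; the posterior covariance is then
computed as a rank-truncated pseudo-inverse so the unidentified direction
contributes zero variance instead of a meaningless 1/ridge.  Consequence:
with a varying intercept in the model, a single category's
constant-plus-own-smooth curve is identified only up to this convention —
the between-level *contrast* a_ℓ(t) − a_ref(t) is what the data pin down.
Odds-ratio curves follow the constant-plus-own-smooth construction, so
their linear-trend component inherits the convention.

## Estimation

Gaussian family: the penalized least squares closed form
γ̂ = (X'X + P)⁻¹X'y with P = blockdiag(λ_j S_j), zero on the unpenalized
constant columns; scale φ̂ = RSS/(n − edf).

Binomial family: penalized IRLS / Fisher scoring on the working response,
equivalent to maximizing l(γ) − ½Σλ_j‖Δ²γ_j‖² (the penalized-deviance
convention: deviance + Σλ_j‖Δ²γ_j‖² is minimized and is non-increasing
across iterations thanks to step halving).  Controls: relative
penalized-deviance tolerance 1e-8, at most 100 iterations, starting value
μ = (y + ½)/2.  With the Gaussian family the loop reproduces the closed
form exactly in one step.  Quasi-separation (|η| > 30 on more than 1% of
rows) triggers a logged 1e-8 ridge on the constant block.

Smoothing parameters: per-smooth λ_j, selected by minimizing GCV
n·D/(n − edf)² (default) or a Laplace-approximate negative restricted
likelihood (REML).  The search is deterministic: a shared-λ sweep over a
log₁₀ grid ([−4, 6], 21 points for standalone fits) followed by joint
Nelder–Mead refinement in log λ (budget 40 evaluations per smooth, capped
at 120).  Inside the model-building pipeline, where dozens of models are
fit per dataset, an 11-point grid with a 25-evaluation refinement is used;
the criterion surface is flat near its optimum and screening decisions
were indistinguishable between the two budgets in calibration runs, while
whole-pipeline studies become several times cheaper.

Effective degrees of freedom: edf = tr[(X'WX + P)⁻¹X'WX] at convergence;
per-term values are the diagonal sums over each term's columns (constant
columns form one pseudo-term), so they add to the total exactly.

## Inference

* AIC = deviance + 2·edf (binomial; conditional AIC) and
  −2·loglik + 2·(edf + 1) (Gaussian, counting the scale).
* Nested models are compared by the likelihood-ratio statistic
  D_null − D_alt (floored at zero) referred to a chi-square with
  *fractional* df = edf_alt − edf_null, evaluated through the
  continuous-df gamma CDF.
* Per-smooth Wald tests use γ̂' V⁻ γ̂ with pseudo-inverse rank equal to
  the rounded term edf.  These p-values are approximate and tend to be
  *underestimated* — the implementation attaches that caveat to every
  result, and fitted curves should be inspected alongside them.
* Credible bands come from the Gaussian posterior N(β̂, φ(X'WX+P)⁻¹)
  implied by viewing the penalty as a prior: analytic ±z·SE pointwise
  bands by default, or ≥10,000 seeded posterior draws.  Bands for
  odds-ratio curves are computed on the combined constant + smooth
  effect and then exponentiated (a monotone map, so ordering is
  preserved).

## Model building

Stage 1 (screening): every covariate in turn — plus the varying
intercept — is given varying coefficients while everything else stays
constant; each model is LRT-tested against the all-constant logistic
model at α = 0.05.  Note that because the reference level keeps a smooth,
each screening model nests a common time trend; with any real drift in
the data, most screening tests fire, and the forward stage does the
actual discrimination (the same pattern arises in the motivating
surveillance analysis).

Stage 2 (forward selection): start from the most significant screened
variable.  Each round fits a Gaussian P-spline model of the current
model's *deviance residuals* on per-level smooths of time for every
remaining screened candidate, scores each by deviance explained
(1 − RSS/TSS), and tests candidates in rank order with the nested LRT,
adding the first significant one; a round with no acceptance stops the
search.  The varying intercept is tested last, and only if it screened
significant.  λ is re-selected for every candidate model.  The full
trace (model, description, p, null model, AIC, edf) is returned and
exported.

Residual type: deviance residuals (the standard GLM choice); whether the
original surveillance analysis used working or deviance residuals is not
documented, and the choice only affects the order in which candidates are
tried, not the likelihood-ratio tests that decide whether one enters.

## Synthetic surveillance generator

`tvcm.synthetic` emulates a PASSI-like design: T = 55 independent monthly
waves (July/August merged upstream is irrelevant here — waves are opaque
equally spaced indices); per wave, `monthly_n` respondents with
categorical covariates drawn independently from fixed marginals; outcome
Bernoulli with logit = intercept + Σ constant effects + Σ varying
effects(wave).  Varying effect shapes (linear, sinusoid, piecewise) are
exactly mean-zero over the waves.  What it does *not* emulate: the
stratified age-by-sex sampling weights, nonresponse, local-health-unit
clustering, or cross-covariate correlation (a joint distribution is not
published; covariates are independent by default).  Passing tests on
these data therefore validate the estimation and selection machinery,
not robustness to survey-design features.

Presets (all intercepts calibrated by exact cell enumeration so the
marginal outcome prevalence is 0.279, the published smoking prevalence):

* `passi-like` — ten covariates with the published marginal shares
  (count-derived); constant log-odds ratios equal to the published
  average ORs; varying effects: the youngest age band declines linearly
  by log(2.1/1.7) ≈ 0.21 over the window, a 0.12 decline for ages 40–49,
  a piecewise accelerating decline of 0.25 for non-drinkers, 0.05 for
  low-risk drinkers, and a 0.08 common decline in the intercept.
* `null` — same composition, nothing varies.
* `dense` — extra varying effects (stress test).
* `bench-small` / `bench-null` — a four-covariate benchmark
  (age in three bands, alcohol, sex, income; monthly_n = 150 by default)
  with pronounced declines (0.7 and 0.6 log-odds) for the young-age and
  non-drinker categories.  Sized by a pre-run power calculation
  (non-centrality ≈ range²/12 × subgroup information ≈ 25–30, i.e.
  single-test power ≈ 99%) so that selection operating characteristics
  are measurable with replicated fits on one CPU.

## Problem sizes used in the test suite and acceptance script

Chosen as the package's own desk-scale study designs: null calibration
uses 500 replicates of n = 5,005 (55 waves × 91, one binary covariate,
k = 55); curve recovery uses one PASSI-like dataset of n = 55,000
(monthly_n = 1,000, k = 55, the generating model refit with GCV);
selection recovery uses 100 benchmark replicates (n = 8,250, k = 10)
plus 40 all-constant replicates; the acceptance script runs reduced
versions (monthly_n = 150, k = 20 pipeline; 40 calibration and 15
recovery replicates).

## Known limitations

* The screening LRT referred to chi-square with edf-difference df is
  anticonservative when λ is selected on the same data: the measured
  null rejection rate at α = 0.05 is about twice nominal in the
  calibration study.  This mirrors the documented behaviour of
  penalized-regression ANOVA tests (and the "p-values tend to be
  underestimated" caveat); at surveillance sample sizes (~2×10⁵) the
  practical impact on screening is small, but exact type-I control
  should not be expected.
* Under an all-constant truth the probability that forward selection
  returns the purely parametric model is bounded by (1 − α_eff)^K for K
  screened candidates — with five candidates and a calibrated 5% test at
  most ≈ 0.77 — so some false varying term is expected in a substantial
  minority of null datasets.  This is a property of the
  per-test-α procedure itself, which performs no multiplicity
  correction.
* Pointwise odds-ratio precision at n = 55,000 is limited: for a
  category with OR ≈ 2 the constant coefficient alone carries a
  posterior SD of ≈ 0.08 on the log scale (≈ 0.16 on the OR scale), so
  individual curve estimates routinely deviate from truth by ~0.2 on
  the OR scale even when the bands cover it.
* With a varying intercept present, the linear-trend component of any
  single category's curve is identified only up to the pinning
  convention described above.
* No survey weights: the sampling design's age-by-sex weighting is not
  modelled, matching the unweighted likelihood of the motivating
  analysis; interactions and multiple effect modifiers are out of scope.
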