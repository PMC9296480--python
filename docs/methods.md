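# Methods

## Models

Both model families describe replicated counts `y_ij` (visit `j` at site
`i`) and differ in how they partition between-site and within-site
variation.

**Count GLMM.** `y_ij ~ D(mu_ij, [theta])` with
`log(mu_ij) = beta0 + x_ij' beta + alpha_i` and
`alpha_i ~ Normal(0, sigma_alpha)`. `D` is Poisson or negative binomial.
`sigma_alpha` is a *standard deviation* throughout (the `N(0, sigma)`
notation is ambiguous in parts of the literature; the SD reading is the
one consistent with the `beta0 + 0.5 sigma_alpha^2` adjustment below).
Because `exp(alpha)` is log-normal, the log of the expected count at the
mean site is `beta0 + 0.5 sigma_alpha^2`, which is the quantity comparable
across model families.

**N-mixture.** Latent abundance `N_i ~ D_b(lambda_i, [theta_b])` with
detections `y_ij ~ D_w(N_i, p_ij, [theta_w])`; `D_b` is Poisson or
negative binomial, `D_w` binomial or beta-binomial, giving variants B-P,
B-NB, BB-P, BB-NB. Parameterizations:

* negative binomial by (mean `lambda`, size `theta_b`), variance
  `lambda + lambda^2/theta_b` (the "nbinom2" convention);
* beta-binomial by (mean `p`, precision `theta_w`), Beta shapes
  `(p theta_w, (1-p) theta_w)`, chosen so that logit-link covariates act
  on mean detection.

Intercepts use the orthogonal rotation `phi1 = log(lambda0 p0)`,
`phi2 = log(p0/lambda0)`, i.e. `p0 = e^{(phi1+phi2)/2}`,
`lambda0 = e^{(phi1-phi2)/2}`. `phi1` is the expected log count at the
mean site; `phi2` isolates the detection-abundance trade-off, so the
well-known likelihood ridge (detection to 0, abundance to infinity) is a
boundary phenomenon in a single coordinate. `phi2` carries a practical
lower bound (default -20, configurable); an estimate within 0.1 of the
bound is flagged and the model is refitted with `phi2` pinned there so the
remaining standard errors are conditional on the boundary.

## Marginal likelihood computation

The N-mixture marginal replaces the infinite sum over `N` with a truncated
sum up to `K` (default `max(1000, 20 x largest observed count)`). Two
backends compute the same quantity:

* **naive** — every term's pmfs evaluated independently (log-gamma per
  term), log-sum-exp over terms;
* **fast** — the first nonzero term (at `N0 = max_j y_ij`) evaluated with
  full log pmfs, then each step `N -> N+1` adds the closed-form log pmf
  ratios (one abundance ratio plus `J` detection ratios, all cheap
  arithmetic and integer-log table lookups, no log-gamma), accumulated by
  a streaming log-sum. Terms are summed from `N0` (all lower terms are
  exactly zero); no early stopping, so results are reproducible
  bit-for-bit across K as long as the retained terms agree.

The fast recursion is implemented both as a compiled (numba) per-site loop
and as a vectorized numpy kernel (used as fallback and as a cross-check);
unit and acceptance tests hold all backends within 1e-8 of the naive sum
over randomized parameters, `J` in 1..20 and `K` in 100..2000. Per-visit
detection probabilities are clipped to `[1e-12, 1 - 1e-12]` so ratio terms
stay finite under extreme linear predictors.

The GLMM marginal integrates the site random effect by adaptive
Gauss-Hermite quadrature: the integrand is recentred at its per-site mode
(Newton steps with analytic first and second derivatives) and rescaled by
the curvature there. The default is 61 nodes: with 25 nodes,
all-zero-count sites combined with `sigma_alpha` near 2 produce integrands
skewed enough to miss a dense-grid oracle by ~1e-5 relative, while 61
nodes holds the worst case near 1e-8 at negligible cost in this vectorized
implementation. A failed mode search falls back to non-adaptive quadrature
with a warning. `sigma_alpha = 0` is evaluated exactly as the fixed-effect
GLM, and an optimizer solution on the `sigma` floor triggers a boundary
refit at `sigma = 0`.

## Fitting, selection, comparison

All six models are fitted by L-BFGS-B with finite-difference gradients
over an internal scale: dispersions and `sigma_alpha` as logs, `(phi1,
phi2)` direct with the box bound on `phi2` and `phi1 + phi2 < 0` enforced
by penalty. Starts: `p0 = 0.5`, `lambda0 = mean(count)/0.5`, slopes 0,
`sigma_alpha = 0.5`, dispersions 1; up to two jittered restarts on
non-convergence. Standard errors come from the inverse of a
central-difference Hessian at the optimum mapped by the delta method; a
singular Hessian yields absent standard errors plus a flag rather than a
failure.

Design preparation centers and scales covariates — site-level covariates
(elevation, land-cover fractions) over the site table, checklist-level
effort covariates over checklist rows — drops covariates with a single
unique value, builds quadratic time-of-day and date terms from the
centered linear columns, and forms pairwise land-cover interactions from
the *raw* fractions, dropping any with Pearson correlation above 0.8 with
either parent (raw products are used because the correlation rule targets
the co-occurrence variable itself; correlation is affine-invariant in each
parent but a product of centered columns is a different variable).

Forward AIC selection starts from the a priori model (elevation plus
duration and observer count; the effort terms sit in the detection
submodel for N-mixtures) and at each step evaluates every admissible
single addition — checklist-level terms to detection only, land-cover
terms and retained interactions to either submodel, quadratics only where
the linear term is already present — accepting the lowest-AIC addition if
it strictly decreases AIC. Detection and abundance moves compete within
the same step; the same term can enter both submodels across successive
steps. The `ΔAIC > 2` threshold is reserved for between-model support
statements (`rank_models`), not for accepting covariates. `n_params`
counts every free parameter including dispersions and `sigma_alpha`, and a
boundary-fixed `phi2` still counts (conservative). AIC ties rank by fewer
parameters.

## Diagnostics

**SSRQ residuals** (N-mixtures): the model pmf of each site's summed
counts is built by convolving the `J` per-visit detection pmfs
conditional on `N` and mixing over the abundance prior, truncated
adaptively where the prior retains all but 1e-10 of its mass (never past
`K`); the pmf's deficiency from 1 equals that tail mass exactly and is
reported. The residual is `Phi^{-1}(u)` with
`u ~ Uniform(F(s_i - 1), F(s_i))` from a seeded generator — exactly
standard normal under the fitted model, one residual per site.

**Simulated quantile residuals** (GLMMs): M = 250 simulated datasets from
the fitted model (fresh random effects each replicate); each observation's
randomized empirical quantile among its simulations, uniform under the
model. Caveat: these are *marginally* uniform but correlated within sites
(shared random effect), so the observation-level KS test over-rejects
under strong clustering — measured ~12% rejection at alpha = 0.01 with
`sigma_alpha = 0.8` and hotspot visit loads, versus the nominal rate in
weak-dependence designs. The calibration preset therefore uses one visit
per site, where the KS independence assumption holds exactly; calibration
results on clustered designs should be read with this inflation in mind.

**Moran's I** uses inverse-distance weights (`1/d_ij`, zero diagonal,
coincident pairs capped at the largest finite weight — a convention, as is
the choice of distance weights over binary neighborhoods), expectation
`-1/(n-1)`, and a two-sided normal-approximation p-value under
randomization; a permutation check in the tests confirms the analytic
p-value within 0.05.

**Stability diagnostic**: the fitted model is refitted at `K0 + 2000` and
`K0 + 4000` (warm-started from the original estimates) and AIC, `phi1`
and `phi2` are each flagged unstable when the two *large-K refits* differ
by more than 0.1 (refit-vs-refit, mirroring the AIC rule; an infinite
tolerance disables all flags). A caveat discovered during development:
with exactly one replicate visit per site the B-P marginal is exactly
Poisson(`lambda0 p0`) by binomial thinning, so the likelihood is flat in
`phi2` to below machine precision and deterministic refits land
identically — a pure single-visit ridge is *invisible* to a
refit-difference diagnostic, even though the flat direction does surface
in the fit itself (singular Hessian / unbounded `phi2` standard error).
Genuine K-dependent drift requires replicated visits whose within-site
variation exceeds the binomial's (then `p -> 0` with `lambda` capped near
`K`), and even there the AIC difference between the two large-K refits is
typically well under 0.1.

## Synthetic data

The generator emulates filtered checklist data: sites on distinct cells of
a 50 m planar grid; clustered visits (a configurable "hotspot" fraction of
sites with mean 20 checklists, the rest mean 2, matching how birding
activity concentrates); elevation standard normal; land cover as four
Dirichlet fractions plus an unstored remainder (so stored fractions sum to
at most 1); duration log-normal around 60 minutes truncated below 240;
observers `1 + Poisson(0.6)` capped at 10; time of day uniform on 5-20 h;
date uniform on days 91-181. Counts are drawn from any of the six models;
covariate effects act on standardized covariate scales (site-level
standardized over sites, checklist-level over checklists — the same
convention the fitting layer uses, so generating coefficients are directly
comparable to estimates). All latent quantities (N_i, p_ij, alpha_i,
mu_ij) are recorded.

What the generator does *not* emulate: spatially autocorrelated habitat,
observer skill heterogeneity, variable effective sampling area, temporal
population change (closure violations), or multi-species structure.
Passing tests on these data therefore certify the estimation and
diagnostic machinery, not robustness to the unmodeled heterogeneity real
checklist data contain.

Presets: `well_identified_bp` (150 sites, ~5 visits, B-P, `phi1 = 0.5`,
`phi2 = -2`, detection effect -0.5 of duration, abundance effect +0.5 of
elevation), `overdispersed_bbp` (100 sites, BB-P, `theta_w = 2`),
`ridge_j1` (100 sites, exactly one visit, B-P), `glmm_nb` (100 sites,
NB-GLMM, `sigma_alpha = 0.8`, `theta = 1.5`), `tiny_toy` (3 sites,
brute-force enumerable), plus the two calibration presets
`bp_gof_calibration` (60 sites, ~3 visits) and `glmm_gof_calibration`
(100 sites, one visit, `sigma_alpha = 0.3`).

## Numerical choices and study sizes

* Truncation default `K = max(1000, 20 x max count)`; stability refits at
  `K + 2000` / `K + 4000` with tolerance 0.1.
* `phi2` lower bound -20; boundary tolerance 0.1.
* Quadrature 61 nodes (see above); Newton mode search capped at 100
  steps, step clipped to ±2.
* Finite-difference Hessian with relative step 1e-4; covariance by direct
  inversion, declared absent if non-finite or with non-positive diagonal.
* Optimizer: L-BFGS-B, maxiter 500, up to 2 restarts jittered by
  N(0, 0.3) on the internal scale.
* Study sizes used by the test suite and `scripts/acceptance.py`:
  1000 draws for backend equivalence; 100 sites for quadrature accuracy;
  200 replicates at 150 sites (plus 100 at 300 sites) for the recovery
  study; 100 replicates per model-selection study; 200 simulated datasets
  per goodness-of-fit calibration meta-test; 20 replicates per stability
  preset; 200 sites per benchmark cell. These sizes make each study's
  Monte-Carlo error small relative to the property being asserted while
  keeping a full run on a single CPU in the minutes range.

## Known limitations

* Wald intervals only; no profile-likelihood or bootstrap intervals.
* No spatially explicit models: Moran's I tests for, but the models do
  not absorb, residual spatial structure.
* The fast-backend speedup factor is hardware- and size-dependent; the
  benchmark reports measured times and asserts only backend agreement.
* Forward selection is greedy; it can miss jointly-supported term sets
  that no single addition reaches.
* The intercept rotation's round trip `(phi1, phi2) -> (lambda0, p0) ->
  (phi1, phi2)` is exact to ~1 ulp, not bit-exact: `exp` and `log` are
  not correctly-rounded inverses in IEEE double.
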