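# relabund

Relative-abundance estimation from replicated count surveys, comparing
**N-mixture models** and **count GLMMs** within one model-selection and
goodness-of-fit workflow.

Ecologists analyzing checklist-style count data (for example filtered
citizen-science point counts) face a choice between two model families
that both partition variation into between-site and within-site
components:

* the **GLMM**: `y_ij ~ D(mu_ij, [theta])` with
  `log(mu_ij) = beta0 + x_ij' beta + alpha_i`, `alpha_i ~ N(0, sigma_alpha)`,
  where `D` is Poisson or negative binomial;
* the **N-mixture model**: latent abundance `N_i ~ D_b(lambda_i, [theta_b])`
  with replicated detections `y_ij ~ D_w(N_i, p_ij, [theta_w])`, giving the
  four variants B-P, B-NB, BB-P and BB-NB (binomial/beta-binomial detection
  crossed with Poisson/negative-binomial abundance), with
  `logit(p_ij) = logit(p0) + x_ij(w) beta_w` and
  `log(lambda_i) = log(lambda0) + x_i(b) beta_b`.

The N-mixture intercepts are handled in the orthogonal rotation
`phi1 = log(lambda0 p0)` (expected log count at the mean site, directly
comparable to the GLMM's `beta0 + 0.5 sigma_alpha^2`) and
`phi2 = log(p0 / lambda0)` (the detection-abundance contrast). The
likelihood ridge that makes N-mixture estimates drift toward zero
detection/"infinite" abundance is confined to `phi2 -> -inf`, where it is
handled as a boundary estimate and probed by a truncation-stability
diagnostic.

What the package provides:

* exact marginalized N-mixture log-likelihoods with two backends — a naive
  truncated sum and a fast incremental-ratio recursion (identical to
  < 1e-8, compiled, no log-gamma calls past the first term);
* GLMM marginal likelihoods by adaptive Gauss–Hermite quadrature;
* maximum-likelihood fitting for all six models with Wald standard errors,
  `phi2` boundary handling, and AIC;
* forward AIC covariate selection with the field's usual rules
  (a priori effort/elevation terms, checklist covariates restricted to the
  detection submodel, interaction-collinearity and constant-covariate
  filters, quadratic-term hierarchy);
* goodness-of-fit via site-sum randomized quantile (SSRQ) residuals for
  N-mixtures and simulated quantile residuals for GLMMs, with KS tests and
  Moran's I on residuals;
* the increase-K stability diagnostic (refits at K+2000 and K+4000,
  instability flagged at |ΔAIC| > 0.1);
* a synthetic checklist-data generator with known truth (clustered visits,
  effort covariates, compositional land cover) and named study presets.

## Worked example

```python
from relabund.synthetic_data import make_fixture
from relabund.model_fitting import (
    FitOptions, ModelSpec, fit_model, prepare_design, rank_models,
    comparable_estimates,
)

fx = make_fixture("well_identified_bp", seed=11)   # B-P truth: phi1=0.5,
bundle = prepare_design(fx["checklists"], fx["sites"])  # phi2=-2, slopes ±0.5

fit = fit_model(fx["spec"], bundle, FitOptions(K=1000))
for k, v in fit.estimates.items():
    print(f"{k:>22}: {v:7.3f}  (se {fit.std_errors[k]:.3f})")
print(f"AIC = {fit.aic:.1f}")
```

prints

```
                  phi1:   0.469  (se 0.053)
                  phi2:  -1.897  (se 0.105)
  det:duration_minutes:  -0.515  (se 0.050)
         abn:elevation:   0.500  (se 0.045)
AIC = 2085.6
```

`phi1 = 0.469` is the estimated log expected count at the mean site (truth
0.5); `phi2 = -1.897` the detection-abundance contrast (truth -2); the
detection effect of standardized duration and the abundance effect of
elevation recover their generating values within one standard error.
`comparable_estimates(fit)` returns the same intercept quantity for any of
the six models so N-mixture and GLMM fits can be compared directly, and
`rank_models([...])` orders fits by AIC with the ΔAIC > 2 support rule.

The same pipeline is scriptable from the shell:

```sh
relabund simulate --preset well_identified_bp --seed 11 --out data/
relabund select --checklists data/checklists.csv --sites data/sites.csv --out sel/
relabund diagnose --checklists data/checklists.csv --sites data/sites.csv \
    --fit sel/fit_nmixture_B-P.json --out diag/
```

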