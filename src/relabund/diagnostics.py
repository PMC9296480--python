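"""Goodness-of-fit, spatial autocorrelation and estimation-stability checks.

N-mixture fits are checked with site-sum randomized quantile (SSRQ)
residuals: the model-implied distribution of each site's summed counts
gives a probability-integral transform that is standard normal when the
model is right.  GLMM fits use simulated quantile residuals (the
randomized empirical quantile of each observation among datasets simulated
from the fitted model), uniform under a correct model.  Both are tested
with one-sample Kolmogorov-Smirnov statistics; Moran's I on the residuals
probes leftover spatial structure.

The stability diagnostic refits an N-mixture at truncation bounds K0+2000
and K0+4000 and flags the fit unstable when AIC (or an intercept) differs
between the two large-K refits by more than a tolerance — the signature of
the detection/abundance likelihood ridge (phi2 drifting toward -inf).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .model_fitting import (
    FitOptions,
    FitResult,
    fit_model,
    glmm_params_from_fit,
    nmix_params_from_fit,
)
from .nmixture_likelihood import (
    VARIANTS,
    SiteObservations,
    _site_linear_predictors,
)

__all__ = [
    "ResidualSet",
    "StabilityReport",
    "site_sum_distribution",
    "ssrq_residuals",
    "simulated_quantile_residuals",
    "ks_gof",
    "morans_i",
    "stability_check",
]


@dataclass
class ResidualSet:
    """Residuals with their reference distribution and optional coordinates."""

    site_ids: list
    residuals: np.ndarray
    reference: str  # 'standard_normal' | 'uniform'
    coords: np.ndarray | None = None
    seed: int | None = None
    flags: dict | None = None

    def to_dict(self) -> dict:
        return {
            "site_ids": [str(s) for s in self.site_ids],
            "residuals": [float(r) for r in self.residuals],
            "reference": self.reference,
            "coords": None if self.coords is None else self.coords.tolist(),
            "seed": self.seed,
            "flags": self.flags or {},
        }


@dataclass
class StabilityReport:
    K_values: tuple
    aics: tuple
    phi1s: tuple
    phi2s: tuple
    aic_unstable: bool
    phi1_unstable: bool
    phi2_unstable: bool
    tolerance: float
    flags: dict

    def to_dict(self) -> dict:
        return {
            "K_values": list(self.K_values),
            "aics": [float(a) for a in self.aics],
            "phi1s": [float(a) for a in self.phi1s],
            "phi2s": [float(a) for a in self.phi2s],
            "aic_unstable": bool(self.aic_unstable),
            "phi1_unstable": bool(self.phi1_unstable),
            "phi2_unstable": bool(self.phi2_unstable),
            "tolerance": float(self.tolerance),
            "flags": self.flags,
        }


def site_sum_distribution(
    fit: FitResult, site: SiteObservations, K: int
) -> tuple[np.ndarray, float]:
    """Model pmf of the summed counts at one site.

    Conditional on latent N, the site sum is the convolution of the J
    per-visit detection pmfs (each supported on 0..N); the marginal mixes
    those conditionals over the abundance prior truncated at K.  Returns
    ``(pmf, tail_mass)`` where ``pmf[s]`` is P(sum = s) for s = 0..J*Ncap
    and ``tail_mass`` is the abundance prior mass beyond the truncation
    actually used — the exact deficiency of the returned pmf from 1.
    """
    if fit.spec.family != "nmixture":
        raise ValueError("site_sum_distribution requires an N-mixture fit")
    variant = VARIANTS[fit.spec.variant]
    params = nmix_params_from_fit(fit)
    lam_i, p_ij = _site_linear_predictors(site, params)
    J = site.n_visits

    n_grid = np.arange(K + 1)
    if variant.between == "poisson":
        ab = stats.poisson.pmf(n_grid, lam_i)
    else:
        tb = params.theta_b
        ab = stats.nbinom.pmf(n_grid, tb, tb / (tb + lam_i))
    # adaptive cap: keep enough of the prior that the truncation error is
    # far below residual resolution, never past K
    cum = np.cumsum(ab)
    above = np.nonzero(cum >= 1.0 - 1e-10)[0]
    ncap = int(above[0]) if above.size else K
    tail_mass = float(1.0 - cum[ncap])

    out = np.zeros(J * ncap + 1)
    for n in range(ncap + 1):
        conv = np.ones(1)
        for j in range(J):
            if variant.within == "binomial":
                d = stats.binom.pmf(np.arange(n + 1), n, p_ij[j])
            else:
                tw = params.theta_w
                d = stats.betabinom.pmf(
                    np.arange(n + 1), n, p_ij[j] * tw, (1.0 - p_ij[j]) * tw
                )
            conv = np.convolve(conv, d)
        out[: conv.size] += ab[n] * conv
    return out, tail_mass


def ssrq_residuals(
    fit: FitResult,
    data: list[SiteObservations],
    seed: int = 0,
    coords: np.ndarray | None = None,
) -> ResidualSet:
    """Site-sum randomized quantile residuals for an N-mixture fit.

    For site sum s_i with model CDF F, draws u ~ Uniform(F(s_i - 1),
    F(s_i)) and returns the standard-normal quantile of u; exactly normal
    under the fitted model.
    """
    rng = np.random.default_rng(seed)
    K = fit.K_used or 1000
    res = np.empty(len(data))
    flags: dict = {}
    for i, site in enumerate(data):
        pmf, tail = site_sum_distribution(fit, site, K)
        if tail > 1e-6:
            flags.setdefault("high_tail_mass_sites", []).append(
                str(site.site_id)
            )
        s = int(site.counts.sum())
        cdf = np.cumsum(pmf)
        hi = cdf[s] if s < cdf.size else 1.0
        lo = cdf[s - 1] if 0 < s <= cdf.size else (0.0 if s == 0 else 1.0)
        if hi <= lo:
            flags.setdefault("degenerate_interval_sites", []).append(
                str(site.site_id)
            )
            u = lo
        else:
            u = rng.uniform(lo, hi)
        res[i] = stats.norm.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))
    return ResidualSet(
        site_ids=[s.site_id for s in data],
        residuals=res,
        reference="standard_normal",
        coords=coords,
        seed=seed,
        flags=flags,
    )


def simulated_quantile_residuals(
    fit: FitResult,
    bundle,
    M: int = 250,
    seed: int = 0,
    coords: np.ndarray | None = None,
) -> ResidualSet:
    """Randomized empirical-quantile residuals for a GLMM fit.

    Simulates M complete datasets from the fitted model (fresh random
    effects each time) and places each observed count within its M
    simulated values, randomizing over ties; uniform under the model.
    """
    if fit.spec.family != "glmm":
        raise ValueError("simulated_quantile_residuals requires a GLMM fit")
    if M < 2:
        raise ValueError("M must be >= 2")
    rng = np.random.default_rng(seed)
    params = glmm_params_from_fit(fit)
    y, X, site_index = bundle.glmm_arrays(fit.spec)
    n_sites = bundle.n_sites
    eta_fix = params.beta0 + X @ params.beta

    alpha = rng.normal(0.0, params.sigma_alpha, size=(M, n_sites))
    mu = np.exp(eta_fix[None, :] + alpha[:, site_index])
    if fit.spec.count_dist == "poisson":
        sims = rng.poisson(mu)
    else:
        th = params.theta
        sims = rng.negative_binomial(th, th / (th + mu))

    below = (sims < y[None, :]).sum(axis=0)
    ties = (sims == y[None, :]).sum(axis=0)
    u = (below + rng.uniform(size=y.size) * (ties + 1.0)) / (M + 1.0)
    return ResidualSet(
        site_ids=list(bundle.checklists.checklist_id)
        if "checklist_id" in bundle.checklists
        else list(range(y.size)),
        residuals=u,
        reference="uniform",
        coords=coords,
        seed=seed,
    )


def ks_gof(res: ResidualSet) -> tuple[float, float]:
    """One-sample KS test against the residual set's reference."""
    r = np.asarray(res.residuals, dtype=float)
    if r.size < 5:
        raise ValueError("need at least 5 residuals")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite residuals")
    ref = "norm" if res.reference == "standard_normal" else "uniform"
    out = stats.kstest(r, ref)
    return float(out.statistic), float(out.pvalue)


def morans_i(values, coords) -> tuple[float, float, float]:
    """Moran's I with inverse-distance weights.

    Weights are w_ij = 1/d_ij with zero diagonal (coincident points get
    the largest finite weight).  Returns (I, E[I] = -1/(n-1), two-sided
    p-value from the normal approximation under randomization).
    """
    z = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = z.size
    if n < 5 or np.unique(xy, axis=0).shape[0] < 5:
        raise ValueError("need at least 5 distinct locations")
    if np.allclose(z, z[0]):
        raise ValueError("constant values: Moran's I undefined")
    d = np.sqrt(
        ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    )
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if np.isinf(w).any():
        cap = w[np.isfinite(w)].max()
        w[np.isinf(w)] = cap

    zc = z - z.mean()
    W = w.sum()
    I = (n / W) * (zc @ w @ zc) / (zc @ zc)
    EI = -1.0 / (n - 1.0)

    S1 = 0.5 * ((w + w.T) ** 2).sum()
    S2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (zc**4).sum() / (zc**2).sum() ** 2
    varI = (
        n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * W**2)
        - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * W**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * W**2) - EI**2
    zscore = (I - EI) / np.sqrt(varI)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return float(I), float(EI), float(p)


def stability_check(
    fit: FitResult,
    bundle,
    deltas: tuple = (2000, 4000),
    tol: float = 0.1,
    options: FitOptions | None = None,
) -> StabilityReport:
    """Refit at K0+deltas and flag quantities that moved between refits.

    Instability flags compare the two large-K refits (not the original
    fit): |value(K0+deltas[1]) - value(K0+deltas[0])| > tol.
    """
    if fit.spec.family != "nmixture":
        raise ValueError("stability_check requires an N-mixture fit")
    if fit.K_used is None:
        raise ValueError("fit has no recorded truncation bound")
    options = options or FitOptions()
    K0 = fit.K_used
    flags: dict = {}

    # warm start on the internal scale of the original fit
    warm = None
    if fit.internal_estimates is not None and not fit.boundary_phi2:
        warm = np.asarray(fit.internal_estimates, dtype=float)

    refits = []
    for dK in deltas:
        opts = replace(options, K=K0 + dK, start=warm)
        try:
            refits.append(fit_model(fit.spec, bundle, opts))
        except Exception as exc:  # noqa: BLE001 - report partial results
            flags[f"refit_K{K0 + dK}_failed"] = str(exc)
            refits.append(None)

    def grab(f, key):
        return np.nan if f is None else f.estimates.get(key, np.nan)

    aics = (fit.aic, *(np.nan if f is None else f.aic for f in refits))
    phi1s = (fit.estimates.get("phi1"), *(grab(f, "phi1") for f in refits))
    phi2s = (fit.estimates.get("phi2"), *(grab(f, "phi2") for f in refits))

    def unstable(vals):
        if np.isinf(tol):
            return False
        a, b = vals[1], vals[2]
        if not (np.isfinite(a) and np.isfinite(b)):
            return True
        return abs(b - a) > tol

    return StabilityReport(
        K_values=(K0, K0 + deltas[0], K0 + deltas[1]),
        aics=aics,
        phi1s=phi1s,
        phi2s=phi2s,
        aic_unstable=unstable(aics),
        phi1_unstable=unstable(phi1s),
        phi2_unstable=unstable(phi2s),
        tolerance=tol,
        flags=flags,
    )
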