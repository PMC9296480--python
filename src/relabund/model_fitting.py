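"""Maximum-likelihood fitting, AIC model comparison and forward selection.

Covers all six models: the four N-mixture variants (B-P, B-NB, BB-P,
BB-NB) and the Poisson / negative-binomial GLMM.  Optimization is
quasi-Newton (L-BFGS-B) with finite-difference gradients over an
unconstrained internal scale: positive parameters (theta_w, theta_b,
sigma_alpha, theta) enter as logs; the rotated N-mixture intercepts
(phi1, phi2) are used directly with a box lower bound on phi2 and the
constraint phi1 + phi2 < 0 enforced by a penalty.  Standard errors come
from the inverse of a central-difference Hessian at the optimum, mapped to
the natural scale by the delta method.

A phi2 estimate that lands on its practical lower bound signals the
detection-abundance likelihood ridge; the fit is flagged and refitted with
phi2 pinned to the bound so the remaining standard errors are conditional
on the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glmm_likelihood as glmm
from .nmixture_likelihood import (
    VARIANTS,
    NMixParams,
    PackedNMixData,
    SiteObservations,
    TruncationBound,
    default_truncation,
    intercepts_from_phi,
    phi_from_intercepts,
)

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "SelectionTrace",
    "ModelRanking",
    "DesignBundle",
    "prepare_design",
    "fit_model",
    "forward_aic_select",
    "rank_models",
    "comparable_estimates",
    "fitresult_from_params",
    "nmix_params_from_fit",
    "glmm_params_from_fit",
    "default_candidate_terms",
    "base_spec",
]

SITE_COVARIATES = (
    "elevation",
    "pct_water",
    "pct_trees",
    "pct_agriculture",
    "pct_other_vegetation",
)
LAND_COVER = SITE_COVARIATES[1:]
CHECKLIST_COVARIATES = (
    "duration_minutes",
    "n_observers",
    "time_of_day",
    "julian_date",
)
QUADRATIC_BASES = ("time_of_day", "julian_date")

_PENALTY = 1e10


@dataclass(frozen=True)
class ModelSpec:
    """Which model, which distributions, which covariates where.

    For N-mixtures, ``detection_terms`` may contain checklist-level effort
    covariates and site-level habitat covariates; ``abundance_terms`` may
    contain only site-level covariates.  The GLMM has a single term list
    (stored in ``abundance_terms``; use the ``terms`` property).
    """

    family: str  # 'glmm' | 'nmixture'
    count_dist: str | None = None  # glmm: 'poisson' | 'negbinom'
    variant: str | None = None  # nmixture: 'B-P' | 'B-NB' | 'BB-P' | 'BB-NB'
    detection_terms: tuple = ()
    abundance_terms: tuple = ()

    def __post_init__(self) -> None:
        if self.family == "glmm":
            if self.count_dist not in ("poisson", "negbinom"):
                raise ValueError("glmm count_dist must be poisson or negbinom")
            if self.detection_terms:
                raise ValueError("glmm has a single term list")
        elif self.family == "nmixture":
            if self.variant not in VARIANTS:
                raise ValueError(f"unknown variant {self.variant!r}")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def glmm(cls, count_dist: str, terms=()) -> "ModelSpec":
        return cls(family="glmm", count_dist=count_dist, abundance_terms=tuple(terms))

    @classmethod
    def nmixture(
        cls, variant: str, detection_terms=(), abundance_terms=()
    ) -> "ModelSpec":
        return cls(
            family="nmixture",
            variant=variant,
            detection_terms=tuple(detection_terms),
            abundance_terms=tuple(abundance_terms),
        )

    @property
    def terms(self) -> tuple:
        """GLMM covariate list."""
        return self.abundance_terms

    @property
    def label(self) -> str:
        if self.family == "glmm":
            return f"glmm:{self.count_dist}"
        return f"nmixture:{self.variant}"


@dataclass
class FitOptions:
    """Tunable fitting knobs with the package defaults."""

    K: int | None = None  # None -> max(1000, 20 * max count)
    start: np.ndarray | None = None
    phi2_lower_bound: float = -20.0
    phi2_boundary_tol: float = 0.1
    n_nodes: int = 61
    backend: str = "fast"
    maxiter: int = 500
    n_restarts: int = 2
    fix_phi2: float | None = None  # boundary-conditioned refits
    seed: int = 0


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict
    std_errors: dict
    loglik: float
    n_params: int
    aic: float
    K_used: int | None
    converged: bool
    boundary_phi2: bool
    flags: dict
    centering_info: dict
    n_obs: int
    n_sites: int
    cov_internal: np.ndarray | None = None
    internal_names: tuple = ()
    internal_estimates: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "spec": {
                "family": self.spec.family,
                "count_dist": self.spec.count_dist,
                "variant": self.spec.variant,
                "detection_terms": list(self.spec.detection_terms),
                "abundance_terms": list(self.spec.abundance_terms),
            },
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "std_errors": {
                k: (None if v is None else float(v))
                for k, v in self.std_errors.items()
            },
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "K_used": self.K_used,
            "converged": bool(self.converged),
            "boundary_phi2": bool(self.boundary_phi2),
            "flags": self.flags,
            "centering_info": {
                k: [float(a), float(b)]
                for k, (a, b) in self.centering_info.items()
            },
            "n_obs": int(self.n_obs),
            "n_sites": int(self.n_sites),
        }


@dataclass
class SelectionTrace:
    steps: list
    chosen: ModelSpec
    base_aic: float

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "chosen": {
                "family": self.chosen.family,
                "count_dist": self.chosen.count_dist,
                "variant": self.chosen.variant,
                "detection_terms": list(self.chosen.detection_terms),
                "abundance_terms": list(self.chosen.abundance_terms),
            },
            "base_aic": float(self.base_aic),
        }


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------


class DesignBundle:
    """Prepared covariates plus the grouped response, ready to fit.

    Site-level covariates are centered/scaled over the site table and
    broadcast to checklists; checklist-level covariates over checklist
    rows.  Interactions among land-cover fractions and quadratic effort
    terms are precomputed; constant covariates and collinear interactions
    are dropped with a logged reason.
    """

    def __init__(
        self,
        checklists: pd.DataFrame,
        sites: pd.DataFrame,
        site_cols: dict,
        obs_cols: dict,
        term_level: dict,
        centering_info: dict,
        dropped: list,
        quadratic_of: dict,
        interactions: tuple,
    ):
        self.checklists = checklists
        self.sites = sites
        self.site_cols = site_cols
        self.obs_cols = obs_cols
        self.term_level = term_level
        self.centering_info = centering_info
        self.dropped = dropped
        self.quadratic_of = quadratic_of
        self.interactions = interactions
        self.site_order = sites.site_id.tolist()
        pos = {s: i for i, s in enumerate(self.site_order)}
        self.site_index = checklists.site_id.map(pos).to_numpy()
        self.counts = checklists["count"].to_numpy(dtype=np.int64)
        self.n_obs = len(checklists)
        self.n_sites = len(sites)

    @property
    def available_terms(self) -> tuple:
        return tuple(self.term_level)

    def obs_matrix(self, terms) -> np.ndarray:
        cols = []
        for t in terms:
            if t not in self.term_level:
                raise KeyError(f"unknown or dropped term {t!r}")
            cols.append(self.obs_cols[t])
        return (
            np.column_stack(cols) if cols else np.zeros((self.n_obs, 0))
        )

    def site_matrix(self, terms) -> np.ndarray:
        cols = []
        for t in terms:
            if t not in self.term_level:
                raise KeyError(f"unknown or dropped term {t!r}")
            if self.term_level[t] != "site":
                raise ValueError(
                    f"checklist-level term {t!r} cannot enter a site-level submodel"
                )
            cols.append(self.site_cols[t])
        return (
            np.column_stack(cols) if cols else np.zeros((self.n_sites, 0))
        )

    def nmix_data(self, spec: ModelSpec) -> list[SiteObservations]:
        xw = self.obs_matrix(spec.detection_terms)
        xb = self.site_matrix(spec.abundance_terms)
        data = []
        for i, sid in enumerate(self.site_order):
            m = self.site_index == i
            if not m.any():
                continue
            data.append(
                SiteObservations(
                    counts=self.counts[m],
                    detection_design=xw[m],
                    abundance_covariates=xb[i],
                    site_id=sid,
                )
            )
        return data

    def glmm_arrays(self, spec: ModelSpec):
        X = self.obs_matrix(spec.terms)
        return self.counts.astype(float), X, self.site_index


def _center_scale(v: np.ndarray, standardize: bool):
    mean = float(v.mean())
    sd = float(v.std())
    if standardize and sd > 0:
        return (v - mean) / sd, (mean, sd)
    return v - mean, (mean, 1.0)


def prepare_design(
    checklists: pd.DataFrame,
    sites: pd.DataFrame,
    standardize: bool = True,
) -> DesignBundle:
    """Build the centered/filtered covariate pool for model fitting."""
    missing = [
        c
        for c in ("site_id", "count", *CHECKLIST_COVARIATES)
        if c not in checklists.columns
    ]
    missing += [
        c for c in ("site_id", *SITE_COVARIATES) if c not in sites.columns
    ]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    unknown_sites = set(checklists.site_id) - set(sites.site_id)
    if unknown_sites:
        raise ValueError(f"checklists reference unknown sites: {sorted(unknown_sites)[:5]}")
    sites = sites.reset_index(drop=True)
    checklists = checklists.reset_index(drop=True)
    pos = {s: i for i, s in enumerate(sites.site_id)}
    obs_site = checklists.site_id.map(pos).to_numpy()

    site_cols: dict[str, np.ndarray] = {}
    obs_cols: dict[str, np.ndarray] = {}
    term_level: dict[str, str] = {}
    centering: dict[str, tuple] = {}
    dropped: list[tuple] = []

    def add_site(name, values):
        if np.unique(values).size <= 1:
            dropped.append((name, "single unique value"))
            return
        v, info = _center_scale(values, standardize)
        site_cols[name] = v
        obs_cols[name] = v[obs_site]
        term_level[name] = "site"
        centering[name] = info

    def add_obs(name, values):
        if np.unique(values).size <= 1:
            dropped.append((name, "single unique value"))
            return
        v, info = _center_scale(values, standardize)
        obs_cols[name] = v
        term_level[name] = "checklist"
        centering[name] = info

    for name in SITE_COVARIATES:
        add_site(name, sites[name].to_numpy(dtype=float))
    for name in CHECKLIST_COVARIATES:
        add_obs(name, checklists[name].to_numpy(dtype=float))

    # quadratic effort terms, built from the centered linear columns
    quadratic_of = {}
    for base in QUADRATIC_BASES:
        if base not in term_level:
            continue
        name = f"{base}_sq"
        add_obs(name, obs_cols[base] ** 2)
        if name in term_level:
            quadratic_of[name] = base

    # pairwise land-cover interactions; drop if collinear with a parent.
    # Products and correlations are taken on the raw fractions (correlation
    # is affine-invariant per variable, but a product of centered columns
    # would be a different variable than the raw co-occurrence).
    interactions = []
    present_lc = [c for c in LAND_COVER if c in term_level]
    for a_i in range(len(present_lc)):
        for b_i in range(a_i + 1, len(present_lc)):
            a, b = present_lc[a_i], present_lc[b_i]
            name = f"{a}:{b}"
            prod = sites[a].to_numpy(dtype=float) * sites[b].to_numpy(
                dtype=float
            )
            if np.unique(prod).size <= 1:
                dropped.append((name, "single unique value"))
                continue
            r = max(
                abs(np.corrcoef(prod, sites[a].to_numpy(dtype=float))[0, 1]),
                abs(np.corrcoef(prod, sites[b].to_numpy(dtype=float))[0, 1]),
            )
            if r > 0.8:
                dropped.append(
                    (name, f"correlation {r:.3f} > 0.8 with a first-order term")
                )
                continue
            v, info = _center_scale(prod, standardize)
            site_cols[name] = v
            obs_cols[name] = v[obs_site]
            term_level[name] = "site"
            centering[name] = info
            interactions.append(name)

    return DesignBundle(
        checklists,
        sites,
        site_cols,
        obs_cols,
        term_level,
        centering,
        dropped,
        quadratic_of,
        tuple(interactions),
    )


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


def _fd_hessian(f, x, rel_step=1e-4):
    d = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _safe_cov(H):
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None
    return cov


def _minimize(nll, x0, bounds, options: FitOptions):
    from scipy.optimize import minimize

    rng = np.random.default_rng(options.seed)
    best = None
    for attempt in range(options.n_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, size=x0.size)
        start = np.clip(
            start,
            [b[0] if b[0] is not None else -np.inf for b in bounds],
            [b[1] if b[1] is not None else np.inf for b in bounds],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                nll,
                start,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.maxiter, "maxfun": 10 * options.maxiter},
            )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success:
            if res is not best and abs(res.fun - best.fun) < 1e-6:
                best = res
            break
    return best


def _fit_nmixture(spec, bundle, options: FitOptions) -> FitResult:
    variant = VARIANTS[spec.variant]
    for t in spec.abundance_terms:
        if bundle.term_level.get(t) == "checklist":
            raise ValueError(
                f"checklist-level term {t!r} not allowed in the abundance submodel"
            )
    data = bundle.nmix_data(spec)
    packed = PackedNMixData(data)
    K = options.K if options.K is not None else default_truncation(bundle.counts).K
    bound = TruncationBound(K)

    pw = len(spec.detection_terms)
    pb = len(spec.abundance_terms)
    fix_phi2 = options.fix_phi2
    names = ["phi1"]
    if fix_phi2 is None:
        names.append("phi2")
    names += [f"det:{t}" for t in spec.detection_terms]
    names += [f"abn:{t}" for t in spec.abundance_terms]
    if variant.has_theta_w:
        names.append("log_theta_w")
    if variant.has_theta_b:
        names.append("log_theta_b")

    def unpack(x):
        i = 0
        phi1 = x[i]; i += 1
        if fix_phi2 is None:
            phi2 = x[i]; i += 1
        else:
            phi2 = fix_phi2
        bw = x[i : i + pw]; i += pw
        bb = x[i : i + pb]; i += pb
        tw = np.exp(x[i]) if variant.has_theta_w else None
        i += variant.has_theta_w
        tb = np.exp(x[i]) if variant.has_theta_b else None
        return phi1, phi2, bw, bb, tw, tb

    def nll(x):
        phi1, phi2, bw, bb, tw, tb = unpack(x)
        s = phi1 + phi2
        if s >= -1e-9:
            return _PENALTY * (1.0 + s)
        try:
            params = NMixParams(
                phi1=phi1, phi2=phi2, beta_w=bw, beta_b=bb,
                theta_w=tw, theta_b=tb,
            )
            ll = packed.loglik(params, variant, bound, options.backend)
        except (ValueError, FloatingPointError, OverflowError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    if options.start is not None:
        x0 = np.asarray(options.start, dtype=float)
    else:
        p0_start = 0.5
        lam0_start = max(bundle.counts.mean(), 0.05) / p0_start
        phi1_0, phi2_0 = phi_from_intercepts(lam0_start, p0_start)
        x0 = [phi1_0]
        if fix_phi2 is None:
            x0.append(max(phi2_0, options.phi2_lower_bound + 1.0))
        x0 += [0.0] * (pw + pb)
        x0 += [0.0] * (variant.has_theta_w + variant.has_theta_b)
        x0 = np.asarray(x0, dtype=float)

    bounds: list[tuple] = [(None, None)] * x0.size
    if fix_phi2 is None:
        bounds[1] = (options.phi2_lower_bound, None)

    res = _minimize(nll, x0, bounds, options)
    xhat = res.x
    loglik = -float(res.fun)
    flags: dict = {"optimizer_message": str(res.message)}

    boundary = False
    if fix_phi2 is None:
        phi2_hat = xhat[1]
        if phi2_hat - options.phi2_lower_bound < options.phi2_boundary_tol:
            boundary = True

    n_params = x0.size + (1 if fix_phi2 is not None else 0)
    if boundary:
        # condition on the boundary for the remaining standard errors
        sub = replace(
            options, fix_phi2=options.phi2_lower_bound, start=None, K=K
        )
        cond = _fit_nmixture(spec, bundle, sub)
        estimates = dict(cond.estimates)
        estimates["phi2"] = options.phi2_lower_bound
        std_errors = dict(cond.std_errors)
        std_errors["phi2"] = None
        flags["phi2_conditional_se"] = True
        return FitResult(
            spec=spec,
            estimates=estimates,
            std_errors=std_errors,
            loglik=cond.loglik,
            n_params=x0.size,  # phi2 still counted (conservative)
            aic=-2.0 * cond.loglik + 2.0 * x0.size,
            K_used=K,
            converged=bool(res.success and cond.converged),
            boundary_phi2=True,
            flags=flags,
            centering_info=bundle.centering_info,
            n_obs=bundle.n_obs,
            n_sites=bundle.n_sites,
            cov_internal=cond.cov_internal,
            internal_names=cond.internal_names,
            internal_estimates=cond.internal_estimates,
        )

    cov = _safe_cov(_fd_hessian(nll, xhat))
    estimates: dict = {}
    std_errors: dict = {}
    phi1, phi2, bw, bb, tw, tb = unpack(xhat)
    natural = {"phi1": phi1}
    if fix_phi2 is None:
        natural["phi2"] = phi2
    for k, t in enumerate(spec.detection_terms):
        natural[f"det:{t}"] = bw[k]
    for k, t in enumerate(spec.abundance_terms):
        natural[f"abn:{t}"] = bb[k]
    if variant.has_theta_w:
        natural["theta_w"] = tw
    if variant.has_theta_b:
        natural["theta_b"] = tb
    estimates.update(natural)
    if fix_phi2 is not None:
        estimates["phi2"] = fix_phi2

    if cov is None:
        flags["singular_hessian"] = True
        std_errors = {k: None for k in estimates}
    else:
        se_int = np.sqrt(np.diag(cov))
        for i, nm in enumerate(names):
            if nm == "log_theta_w":
                std_errors["theta_w"] = se_int[i] * tw
            elif nm == "log_theta_b":
                std_errors["theta_b"] = se_int[i] * tb
            else:
                std_errors[nm] = se_int[i]
        if fix_phi2 is not None:
            std_errors["phi2"] = None

    return FitResult(
        spec=spec,
        estimates=estimates,
        std_errors=std_errors,
        loglik=loglik,
        n_params=n_params,
        aic=-2.0 * loglik + 2.0 * n_params,
        K_used=K,
        converged=bool(res.success),
        boundary_phi2=False,
        flags=flags,
        centering_info=bundle.centering_info,
        n_obs=bundle.n_obs,
        n_sites=bundle.n_sites,
        cov_internal=cov,
        internal_names=tuple(names),
        internal_estimates=xhat.copy(),
    )


_SIGMA_FLOOR = 1e-6


def _fit_glmm(spec, bundle, options: FitOptions) -> FitResult:
    y, X, site_index = bundle.glmm_arrays(spec)
    family = spec.count_dist
    p = X.shape[1]
    has_theta = family == "negbinom"
    names = ["beta0"] + list(spec.terms) + ["log_sigma_alpha"]
    if has_theta:
        names.append("log_theta")

    def unpack(x):
        beta0 = x[0]
        beta = x[1 : 1 + p]
        sigma = np.exp(x[1 + p])
        theta = np.exp(x[2 + p]) if has_theta else None
        return beta0, beta, sigma, theta

    def nll(x, sigma_zero=False):
        beta0, beta, sigma, theta = unpack(x)
        if sigma_zero:
            sigma = 0.0
        eta = beta0 + X @ beta
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ll = float(
                    glmm._site_marginal_batch(
                        y, eta, site_index, bundle.n_sites, sigma,
                        family, theta, options.n_nodes,
                    ).sum()
                )
        except (ValueError, FloatingPointError, OverflowError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    if options.start is not None:
        x0 = np.asarray(options.start, dtype=float)
    else:
        x0 = np.concatenate(
            [
                [np.log(max(y.mean(), 0.05))],
                np.zeros(p),
                [np.log(0.5)],
                [0.0] if has_theta else [],
            ]
        )
    bounds: list[tuple] = [(None, None)] * (1 + p)
    bounds.append((np.log(_SIGMA_FLOOR), np.log(50.0)))
    if has_theta:
        bounds.append((np.log(1e-4), np.log(1e7)))

    res = _minimize(nll, x0, bounds, options)
    xhat = res.x
    loglik = -float(res.fun)
    flags: dict = {"optimizer_message": str(res.message)}
    beta0, beta, sigma, theta = unpack(xhat)

    boundary_sigma = xhat[1 + p] < np.log(_SIGMA_FLOOR) + 0.5
    if boundary_sigma:
        # sigma on its floor: treat as sigma = 0 (GLM) and refit freely
        from scipy.optimize import minimize as _m

        def nll0(z):
            zz = np.concatenate([z[: 1 + p], [np.log(_SIGMA_FLOOR)], z[1 + p :]])
            return nll(zz, sigma_zero=True)

        z0 = np.concatenate([xhat[: 1 + p], xhat[2 + p :]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res0 = _m(nll0, z0, method="L-BFGS-B")
        if -res0.fun >= loglik - 1e-8:
            flags["sigma_alpha_boundary"] = True
            zhat = res0.x
            loglik = -float(res0.fun)
            beta0 = zhat[0]
            beta = zhat[1 : 1 + p]
            sigma = 0.0
            theta = np.exp(zhat[1 + p]) if has_theta else None
            cov0 = _safe_cov(_fd_hessian(nll0, zhat))
            estimates = {"beta0": beta0}
            for k, t in enumerate(spec.terms):
                estimates[t] = beta[k]
            estimates["sigma_alpha"] = 0.0
            if has_theta:
                estimates["theta"] = theta
            if cov0 is None:
                flags["singular_hessian"] = True
                std_errors = {k: None for k in estimates}
            else:
                se = np.sqrt(np.diag(cov0))
                std_errors = {"beta0": se[0]}
                for k, t in enumerate(spec.terms):
                    std_errors[t] = se[1 + k]
                std_errors["sigma_alpha"] = None
                if has_theta:
                    std_errors["theta"] = se[1 + p] * theta
            n_params = xhat.size  # sigma still counted
            zn = ["beta0"] + list(spec.terms) + (["log_theta"] if has_theta else [])
            return FitResult(
                spec=spec,
                estimates=estimates,
                std_errors=std_errors,
                loglik=loglik,
                n_params=n_params,
                aic=-2.0 * loglik + 2.0 * n_params,
                K_used=None,
                converged=bool(res0.success),
                boundary_phi2=False,
                flags=flags,
                centering_info=bundle.centering_info,
                n_obs=bundle.n_obs,
                n_sites=bundle.n_sites,
                cov_internal=cov0,
                internal_names=tuple(zn),
                internal_estimates=zhat.copy(),
            )

    cov = _safe_cov(_fd_hessian(nll, xhat))
    estimates = {"beta0": beta0}
    for k, t in enumerate(spec.terms):
        estimates[t] = beta[k]
    estimates["sigma_alpha"] = sigma
    if has_theta:
        estimates["theta"] = theta
    if cov is None:
        flags["singular_hessian"] = True
        std_errors = {k: None for k in estimates}
    else:
        se = np.sqrt(np.diag(cov))
        std_errors = {"beta0": se[0]}
        for k, t in enumerate(spec.terms):
            std_errors[t] = se[1 + k]
        std_errors["sigma_alpha"] = se[1 + p] * sigma
        if has_theta:
            std_errors["theta"] = se[2 + p] * theta
    n_params = xhat.size
    return FitResult(
        spec=spec,
        estimates=estimates,
        std_errors=std_errors,
        loglik=loglik,
        n_params=n_params,
        aic=-2.0 * loglik + 2.0 * n_params,
        K_used=None,
        converged=bool(res.success),
        boundary_phi2=False,
        flags=flags,
        centering_info=bundle.centering_info,
        n_obs=bundle.n_obs,
        n_sites=bundle.n_sites,
        cov_internal=cov,
        internal_names=tuple(names),
        internal_estimates=xhat.copy(),
    )


def fit_model(
    spec: ModelSpec, bundle: DesignBundle, options: FitOptions | None = None
) -> FitResult:
    """Fit one model by maximum likelihood and return the full result."""
    options = options or FitOptions()
    if spec.family == "nmixture":
        return _fit_nmixture(spec, bundle, options)
    return _fit_glmm(spec, bundle, options)


# ---------------------------------------------------------------------------
# forward AIC selection and model comparison
# ---------------------------------------------------------------------------

A_PRIORI_SITE = ("elevation",)
A_PRIORI_CHECKLIST = ("duration_minutes", "n_observers")


def base_spec(family: str, dist: str, bundle: DesignBundle) -> ModelSpec:
    """The a priori model every selection run starts from.

    Elevation plus the two effort covariates; for N-mixtures the effort
    covariates sit in the detection submodel and elevation in abundance.
    """
    site_terms = tuple(t for t in A_PRIORI_SITE if t in bundle.term_level)
    obs_terms = tuple(t for t in A_PRIORI_CHECKLIST if t in bundle.term_level)
    if family == "glmm":
        return ModelSpec.glmm(dist, terms=site_terms + obs_terms)
    return ModelSpec.nmixture(
        dist, detection_terms=obs_terms, abundance_terms=site_terms
    )


def default_candidate_terms(bundle: DesignBundle) -> tuple:
    """Candidate pool: land cover, retained interactions, quadratic effort."""
    cands = [c for c in LAND_COVER if c in bundle.term_level]
    cands += list(bundle.interactions)
    cands += [q for q in bundle.quadratic_of if q in bundle.term_level]
    cands += [
        t
        for t in ("time_of_day", "julian_date")
        if t in bundle.term_level
    ]
    return tuple(cands)


def _admissible_moves(spec: ModelSpec, candidates, bundle: DesignBundle):
    moves = []
    for term in candidates:
        if term not in bundle.term_level:
            continue
        level = bundle.term_level[term]
        linear = bundle.quadratic_of.get(term)
        if spec.family == "glmm":
            if term in spec.terms:
                continue
            if linear is not None and linear not in spec.terms:
                continue
            moves.append((term, "terms"))
        else:
            submodels = []
            if level == "checklist":
                submodels = ["detection"]
            else:
                submodels = ["detection", "abundance"]
            for sub in submodels:
                have = (
                    spec.detection_terms
                    if sub == "detection"
                    else spec.abundance_terms
                )
                if term in have:
                    continue
                if linear is not None and linear not in have:
                    continue
                moves.append((term, sub))
    return moves


def _apply_move(spec: ModelSpec, term: str, submodel: str) -> ModelSpec:
    if spec.family == "glmm":
        return replace(spec, abundance_terms=spec.terms + (term,))
    if submodel == "detection":
        return replace(spec, detection_terms=spec.detection_terms + (term,))
    return replace(spec, abundance_terms=spec.abundance_terms + (term,))


def forward_aic_select(
    base: ModelSpec,
    candidates,
    bundle: DesignBundle,
    options: FitOptions | None = None,
) -> tuple[SelectionTrace, FitResult]:
    """Greedy forward selection: accept the best AIC-lowering addition.

    Detection and abundance candidate moves are pooled and compared in the
    same step.  A candidate whose fit fails to converge is skipped and
    logged, never fatal.
    """
    options = options or FitOptions()
    current = fit_model(base, bundle, options)
    base_aic = current.aic
    steps: list[dict] = []
    spec = base
    while True:
        moves = _admissible_moves(spec, candidates, bundle)
        if not moves:
            break
        results = []
        for term, sub in moves:
            cand_spec = _apply_move(spec, term, sub)
            try:
                fit = fit_model(cand_spec, bundle, options)
            except Exception as exc:  # noqa: BLE001 - selection must survive
                steps.append(
                    {
                        "term": term,
                        "submodel": sub,
                        "aic": None,
                        "accepted": False,
                        "error": str(exc),
                    }
                )
                continue
            if not fit.converged:
                steps.append(
                    {
                        "term": term,
                        "submodel": sub,
                        "aic": float(fit.aic),
                        "accepted": False,
                        "error": "did not converge",
                    }
                )
                continue
            results.append((term, sub, fit))
        if not results:
            break
        term, sub, fit = min(results, key=lambda r: r[2].aic)
        for t, s, f in results:
            if (t, s) != (term, sub):
                steps.append(
                    {"term": t, "submodel": s, "aic": float(f.aic), "accepted": False}
                )
        if fit.aic < current.aic:
            steps.append(
                {
                    "term": term,
                    "submodel": sub,
                    "aic": float(fit.aic),
                    "accepted": True,
                }
            )
            spec = fit.spec
            current = fit
        else:
            steps.append(
                {"term": term, "submodel": sub, "aic": float(fit.aic), "accepted": False}
            )
            break
    return SelectionTrace(steps=steps, chosen=spec, base_aic=base_aic), current


@dataclass
class ModelRanking:
    table: pd.DataFrame
    best_label: str
    contrast: dict

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "best_label": self.best_label,
            "contrast": self.contrast,
        }


def rank_models(fits: list[FitResult]) -> ModelRanking:
    """Order fits by AIC; flag clear support (delta AIC > 2).

    Also reports the best-N-mixture vs best-GLMM contrast, the comparison
    of primary interest when both families are on the table.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits are not on the same dataset (n differs)")
    ordered = sorted(fits, key=lambda f: (f.aic, f.n_params))
    best = ordered[0]
    rows = []
    for rank, f in enumerate(ordered, start=1):
        delta = f.aic - best.aic
        rows.append(
            {
                "rank": rank,
                "model": f.spec.label,
                "aic": f.aic,
                "delta_aic": delta,
                "n_params": f.n_params,
                "clearly_worse_than_best": delta > 2.0,
            }
        )
    nmix = [f for f in fits if f.spec.family == "nmixture"]
    glmms = [f for f in fits if f.spec.family == "glmm"]
    contrast: dict = {}
    if nmix and glmms:
        bn = min(nmix, key=lambda f: f.aic)
        bg = min(glmms, key=lambda f: f.aic)
        delta = bg.aic - bn.aic  # positive -> N-mixture better
        supported = None
        if delta > 2.0:
            supported = "nmixture"
        elif delta < -2.0:
            supported = "glmm"
        contrast = {
            "best_nmixture": bn.spec.label,
            "best_glmm": bg.spec.label,
            "delta_aic_glmm_minus_nmixture": float(delta),
            "clearly_supported": supported,
        }
    return ModelRanking(
        table=pd.DataFrame(rows), best_label=best.spec.label, contrast=contrast
    )


def fitresult_from_params(
    spec: ModelSpec, params, n_obs: int = 0, n_sites: int = 0, K: int | None = 1000
) -> FitResult:
    """Wrap explicit parameters as a FitResult, without fitting.

    Lets the diagnostics run under hypothesized (for instance, true
    generating) parameters: residual calibration checks evaluate the
    model distribution at known truth rather than at an estimate.
    """
    est: dict = {}
    if spec.family == "nmixture":
        est["phi1"] = float(params.phi1)
        est["phi2"] = float(params.phi2)
        for t, v in zip(spec.detection_terms, params.beta_w):
            est[f"det:{t}"] = float(v)
        for t, v in zip(spec.abundance_terms, params.beta_b):
            est[f"abn:{t}"] = float(v)
        if params.theta_w is not None:
            est["theta_w"] = float(params.theta_w)
        if params.theta_b is not None:
            est["theta_b"] = float(params.theta_b)
    else:
        est["beta0"] = float(params.beta0)
        for t, v in zip(spec.terms, params.beta):
            est[t] = float(v)
        est["sigma_alpha"] = float(params.sigma_alpha)
        if params.theta is not None:
            est["theta"] = float(params.theta)
        K = None
    return FitResult(
        spec=spec,
        estimates=est,
        std_errors={k: None for k in est},
        loglik=np.nan,
        n_params=len(est),
        aic=np.nan,
        K_used=K,
        converged=True,
        boundary_phi2=False,
        flags={"from_params": True},
        centering_info={},
        n_obs=n_obs,
        n_sites=n_sites,
    )


def nmix_params_from_fit(fit: FitResult) -> NMixParams:
    """Rebuild the NMixParams vector stored in a fit's estimate table."""
    if fit.spec.family != "nmixture":
        raise ValueError("not an N-mixture fit")
    est = fit.estimates
    return NMixParams(
        phi1=est["phi1"],
        phi2=est["phi2"],
        beta_w=[est[f"det:{t}"] for t in fit.spec.detection_terms],
        beta_b=[est[f"abn:{t}"] for t in fit.spec.abundance_terms],
        theta_w=est.get("theta_w"),
        theta_b=est.get("theta_b"),
    )


def glmm_params_from_fit(fit: FitResult) -> glmm.GLMMParams:
    """Rebuild the GLMMParams vector stored in a fit's estimate table."""
    if fit.spec.family != "glmm":
        raise ValueError("not a GLMM fit")
    est = fit.estimates
    return glmm.GLMMParams(
        beta0=est["beta0"],
        beta=[est[t] for t in fit.spec.terms],
        sigma_alpha=est["sigma_alpha"],
        theta=est.get("theta"),
    )


def comparable_estimates(fit: FitResult) -> dict:
    """Cross-family comparable quantities.

    Log expected count at the mean site — phi1 for an N-mixture,
    beta0 + 0.5 sigma_alpha^2 (delta-method SE) for a GLMM — plus the
    elevation coefficient, the shared relative-abundance driver.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    out: dict = {"conditional_on_boundary": False}
    if fit.spec.family == "nmixture":
        out["log_expected_count"] = fit.estimates["phi1"]
        out["log_expected_count_se"] = fit.std_errors.get("phi1")
        out["elevation_coef"] = fit.estimates.get("abn:elevation")
        out["elevation_se"] = fit.std_errors.get("abn:elevation")
        out["conditional_on_boundary"] = fit.boundary_phi2
    else:
        beta0 = fit.estimates["beta0"]
        sigma = fit.estimates["sigma_alpha"]
        out["log_expected_count"] = glmm.expected_log_count(beta0, sigma)
        se = None
        if fit.cov_internal is not None and "log_sigma_alpha" in fit.internal_names:
            i0 = fit.internal_names.index("beta0")
            i1 = fit.internal_names.index("log_sigma_alpha")
            v = fit.cov_internal
            # d/dbeta0 = 1; d/dlog sigma = sigma^2
            var = (
                v[i0, i0]
                + sigma**4 * v[i1, i1]
                + 2.0 * sigma**2 * v[i0, i1]
            )
            se = float(np.sqrt(var)) if var > 0 else None
        elif fit.std_errors.get("beta0") is not None:
            se = fit.std_errors["beta0"]
            out["conditional_on_boundary"] = True
        out["log_expected_count_se"] = se
        out["elevation_coef"] = fit.estimates.get("elevation")
        out["elevation_se"] = fit.std_errors.get("elevation")
    return out
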