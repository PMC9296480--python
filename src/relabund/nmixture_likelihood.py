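"""Marginal N-mixture log-likelihoods.

The N-mixture model marginalizes a latent per-site abundance N_i out of the
joint distribution of the replicate counts at that site:

    y_ij ~ D_w(N_i, p_ij, [theta_w])        (within-site / detection)
    N_i  ~ D_b(lambda_i, [theta_b])         (between-site / abundance)

The infinite sum over N is truncated at a conservatively large bound K.
Two backends compute the same quantity:

* ``naive`` — evaluate every term's pmfs independently and log-sum them;
* ``fast``  — evaluate the full pmfs once at the first non-zero term
  N0 = max(y_i.), then advance N with the closed-form log pmf ratios, so
  each step costs O(J) cheap arithmetic with no log-gamma calls.

Intercepts use the orthogonal rotation phi1 = log(lambda0 * p0) (expected
log count at the mean site) and phi2 = log(p0 / lambda0) (detection vs
abundance contrast), i.e. p0 = e^{(phi1+phi2)/2}, lambda0 = e^{(phi1-phi2)/2}.
A likelihood ridge toward zero detection is then confined to phi2 -> -inf.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit, gammaln, logit, logsumexp

try:  # compiled incremental-ratio kernel; numpy fallback below
    from ._fast_kernels import nmix_fast as _nmix_fast_compiled
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _nmix_fast_compiled = None

from .count_distributions import (
    AbundanceDist,
    DetectionDist,
    StreamLogSum,
    abundance_log_pmf,
    abundance_log_ratio,
    detection_log_pmf,
    detection_log_ratio,
)

__all__ = [
    "VARIANTS",
    "NMixtureVariant",
    "NMixParams",
    "SiteObservations",
    "TruncationBound",
    "intercepts_from_phi",
    "phi_from_intercepts",
    "site_loglik_naive",
    "site_loglik_fast",
    "dataset_loglik",
    "PackedNMixData",
    "benchmark_backends",
    "default_truncation",
]


@dataclass(frozen=True)
class NMixtureVariant:
    """One of the four submodel combinations (B-P, B-NB, BB-P, BB-NB)."""

    name: str
    within: str  # 'binomial' | 'betabinom'
    between: str  # 'poisson' | 'negbinom'

    @property
    def has_theta_w(self) -> bool:
        return self.within == "betabinom"

    @property
    def has_theta_b(self) -> bool:
        return self.between == "negbinom"


VARIANTS: dict[str, NMixtureVariant] = {
    "B-P": NMixtureVariant("B-P", "binomial", "poisson"),
    "B-NB": NMixtureVariant("B-NB", "binomial", "negbinom"),
    "BB-P": NMixtureVariant("BB-P", "betabinom", "poisson"),
    "BB-NB": NMixtureVariant("BB-NB", "betabinom", "negbinom"),
}


def _as_variant(variant) -> NMixtureVariant:
    if isinstance(variant, NMixtureVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown N-mixture variant {variant!r}; choose from {sorted(VARIANTS)}"
        ) from None


@dataclass
class NMixParams:
    """Parameter vector of an N-mixture model in the rotated intercepts.

    beta_w act on logit detection per visit; beta_b on log abundance per
    site.  theta_w / theta_b are present only for the beta-binomial /
    negative-binomial submodels.
    """

    phi1: float
    phi2: float
    beta_w: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_b: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_w: float | None = None
    theta_b: float | None = None

    def __post_init__(self) -> None:
        self.beta_w = np.atleast_1d(np.asarray(self.beta_w, dtype=float))
        self.beta_b = np.atleast_1d(np.asarray(self.beta_b, dtype=float))
        if self.phi1 + self.phi2 >= 0:
            raise ValueError("phi1 + phi2 must be < 0 (p0 < 1)")
        for name in ("theta_w", "theta_b"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass
class SiteObservations:
    """Replicate counts at one site with aligned design information."""

    counts: np.ndarray
    detection_design: np.ndarray | None = None
    abundance_covariates: np.ndarray | None = None
    site_id: str | int | None = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_1d(np.asarray(self.counts, dtype=np.int64))
        if self.counts.size == 0:
            raise ValueError("a site must have at least one visit")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        j = self.counts.size
        if self.detection_design is None:
            self.detection_design = np.zeros((j, 0))
        else:
            self.detection_design = np.atleast_2d(
                np.asarray(self.detection_design, dtype=float)
            )
            if self.detection_design.shape[0] != j:
                raise ValueError("detection design rows must align with counts")
        if self.abundance_covariates is None:
            self.abundance_covariates = np.zeros(0)
        else:
            self.abundance_covariates = np.atleast_1d(
                np.asarray(self.abundance_covariates, dtype=float)
            )

    @property
    def n_visits(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class TruncationBound:
    """Upper bound K of the truncated sum over latent abundance."""

    K: int

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be nonnegative")


def default_truncation(counts) -> TruncationBound:
    """Conservative default K = max(1000, 20 x largest observed count)."""
    m = int(np.max(counts)) if np.size(counts) else 0
    return TruncationBound(max(1000, 20 * m))


def intercepts_from_phi(phi1: float, phi2: float) -> tuple[float, float]:
    """Map rotated intercepts to (lambda0, p0).

    p0 = e^{(phi1+phi2)/2} and lambda0 = e^{(phi1-phi2)/2}, so that
    lambda0 * p0 = e^{phi1} and p0 / lambda0 = e^{phi2} exactly.
    """
    if phi1 + phi2 >= 0:
        raise ValueError("phi1 + phi2 must be < 0 so that p0 < 1")
    lam0 = np.exp((phi1 - phi2) / 2.0)
    p0 = np.exp((phi1 + phi2) / 2.0)
    return float(lam0), float(p0)


def phi_from_intercepts(lambda0: float, p0: float) -> tuple[float, float]:
    """Inverse of :func:`intercepts_from_phi`."""
    if not lambda0 > 0:
        raise ValueError("lambda0 must be positive")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    return float(np.log(lambda0 * p0)), float(np.log(p0 / lambda0))


# ---------------------------------------------------------------------------
# batched likelihood kernels: all sites in a group share the same number of
# visits J, so counts are (S, J), detection probabilities (S, J) and
# abundance means (S,).  Vectorizing over the N grid keeps a dataset
# evaluation to a handful of array operations.
# ---------------------------------------------------------------------------


def _abundance_logpmf_grid(n_grid, lam, variant, theta_b):
    # lam: (S,), n_grid: (K+1,) -> (S, K+1)
    if variant.between == "poisson":
        return stats.poisson.logpmf(n_grid[None, :], lam[:, None])
    return stats.nbinom.logpmf(
        n_grid[None, :], theta_b, theta_b / (theta_b + lam[:, None])
    )


def _detection_logpmf_grid(y, n_grid, p, variant, theta_w):
    # y, p: (S, J); n_grid: (K+1,) -> (S, J, K+1); y > n cells are -inf
    if variant.within == "binomial":
        return stats.binom.logpmf(
            y[:, :, None], n_grid[None, None, :], p[:, :, None]
        )
    a = p[:, :, None] * theta_w
    b = (1.0 - p[:, :, None]) * theta_w
    return stats.betabinom.logpmf(y[:, :, None], n_grid[None, None, :], a, b)


def _batch_loglik_naive(y, p, lam, variant, theta_w, theta_b, K):
    n_grid = np.arange(K + 1)
    la = _abundance_logpmf_grid(n_grid, lam, variant, theta_b)
    ld = _detection_logpmf_grid(y, n_grid, p, variant, theta_w)
    return logsumexp(la + ld.sum(axis=1), axis=1)


def _batch_loglik_fast(y, p, lam, variant, theta_w, theta_b, K):
    # Terms below a site's N0 = max(y) never enter the result: the
    # cumulative ratio sum is referenced to N0, so any finite placeholder
    # values in that prefix cancel exactly, and the final -inf mask removes
    # the rows themselves.  This keeps the hot path to one table gather
    # (binomial) or one log (beta-binomial) over the (sites, visits, K)
    # block, with no log-gamma past the anchor terms.
    S, J = y.shape
    ymax = y.max(axis=1)
    n_grid = np.arange(K + 1)

    # anchor term at per-site N0 = max(y): full log pmfs, evaluated once
    if variant.between == "poisson":
        la0 = ymax * np.log(lam) - lam - gammaln(ymax + 1.0)
    else:
        tb = theta_b
        la0 = (
            gammaln(ymax + tb)
            - gammaln(tb)
            - gammaln(ymax + 1.0)
            + tb * np.log(tb / (tb + lam))
            + ymax * np.log(lam / (tb + lam))
        )
    n0 = ymax[:, None].astype(float)
    log_choose = (
        gammaln(n0 + 1.0) - gammaln(y + 1.0) - gammaln(n0 - y + 1.0)
    )
    if variant.within == "binomial":
        ld0 = log_choose + y * np.log(p) + (n0 - y) * np.log1p(-p)
    else:
        a = p * theta_w
        bb = (1.0 - p) * theta_w
        ld0 = log_choose + betaln(y + a, n0 - y + bb) - betaln(a, bb)
    anchor = la0 + ld0.sum(axis=1)

    # closed-form log ratios for steps n -> n+1, n = 0..K-1
    log_int = np.log(np.arange(1, K + 2, dtype=float))  # log_int[m-1]=log m
    log_np1 = log_int[:K]  # log(n+1) for n = 0..K-1
    if variant.between == "poisson":
        ra = np.log(lam)[:, None] - log_np1[None, :]
    else:
        ra = (np.log(n_grid[:K] + theta_b) - log_np1)[None, :] + np.log(
            lam / (lam + theta_b)
        )[:, None]

    if variant.within == "binomial":
        # sum_j [log(n+1) + log(1-p_ij) - log(n+1-y_ij)]
        const = np.log1p(-p).sum(axis=1)  # (S,)
        idx = n_grid[None, None, :K] - y[:, :, None]  # n - y
        gath = log_int[np.clip(idx, 0, None)].sum(axis=1)  # log(n+1-y)
        rd = J * log_np1[None, :] + const[:, None] - gath
    else:
        # a + b = theta_w for every visit, so log(n+a+b) is per-n only
        b = (1.0 - p) * theta_w  # (S, J)
        idx = n_grid[None, None, :K] - y[:, :, None]  # n - y
        t1 = np.log(np.where(idx >= 0, idx + b[:, :, None], 1.0))
        t2 = log_int[np.clip(idx, 0, None)]  # log(n+1-y)
        rd = (
            J * (log_np1 - np.log(n_grid[:K] + theta_w))[None, :]
            + (t1 - t2).sum(axis=1)
        )
    r = ra + rd  # (S, K)

    csum = np.concatenate(
        [np.zeros((S, 1)), np.cumsum(r, axis=1)], axis=1
    )  # csum[:, n] = sum of ratios for steps < n
    terms = anchor[:, None] + csum - csum[np.arange(S), ymax][:, None]
    terms = np.where(n_grid[None, :] >= ymax[:, None], terms, -np.inf)
    return _logsumexp_rows(terms)


def _fast_kernel(y, p, lam, variant, theta_w, theta_b, K):
    """Fast backend dispatch: compiled recursion, else the numpy kernel."""
    if _nmix_fast_compiled is None:
        return _batch_loglik_fast(y, p, lam, variant, theta_w, theta_b, K)
    return _nmix_fast_compiled(
        np.ascontiguousarray(y, dtype=np.int64),
        np.ascontiguousarray(p, dtype=np.float64),
        np.ascontiguousarray(lam, dtype=np.float64),
        int(K),
        variant.within == "betabinom",
        variant.between == "negbinom",
        float(theta_w) if theta_w is not None else 0.0,
        float(theta_b) if theta_b is not None else 0.0,
    )


def _logsumexp_rows(terms):
    m = np.max(terms, axis=1)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    out = m_safe + np.log(
        np.sum(np.exp(terms - m_safe[:, None]), axis=1)
    )
    return np.where(np.isfinite(m), out, -np.inf)


def _dists_for(variant, lam_i, p_ij, theta_w, theta_b):
    ab = AbundanceDist(
        variant.between,
        float(lam_i),
        float(theta_b) if variant.has_theta_b else None,
    )
    det = [
        DetectionDist(
            variant.within,
            float(pj),
            float(theta_w) if variant.has_theta_w else None,
        )
        for pj in np.atleast_1d(p_ij)
    ]
    return ab, det


def _site_linear_predictors(site: SiteObservations, params: NMixParams):
    lam0, p0 = intercepts_from_phi(params.phi1, params.phi2)
    if site.detection_design.shape[1] != params.beta_w.size:
        raise ValueError("detection design / beta_w dimension mismatch")
    if site.abundance_covariates.size != params.beta_b.size:
        raise ValueError("abundance covariates / beta_b dimension mismatch")
    eta_w = logit(p0) + site.detection_design @ params.beta_w
    eta_b = np.log(lam0) + site.abundance_covariates @ params.beta_b
    if not (np.all(np.isfinite(eta_w)) and np.isfinite(eta_b)):
        raise ValueError("non-finite linear predictor")
    # keep probabilities strictly interior so pmf ratios stay finite
    return float(np.exp(eta_b)), np.clip(expit(eta_w), 1e-12, 1.0 - 1e-12)


def site_loglik_naive(
    site: SiteObservations,
    params: NMixParams,
    variant,
    bound: TruncationBound,
) -> float:
    """Truncated-sum site log-likelihood, every term's pmfs from scratch."""
    variant = _as_variant(variant)
    ymax = int(site.counts.max())
    if bound.K < ymax:
        raise ValueError(f"K={bound.K} is below max observed count {ymax}")
    lam_i, p_ij = _site_linear_predictors(site, params)
    ab, det = _dists_for(variant, lam_i, p_ij, params.theta_w, params.theta_b)
    acc = StreamLogSum()
    n_grid = np.arange(ymax, bound.K + 1)
    la = abundance_log_pmf(ab, n_grid)
    ld = np.zeros(n_grid.size)
    for j, d in enumerate(det):
        ld += detection_log_pmf(d, site.counts[j], n_grid)
    for t in np.atleast_1d(la + ld):
        acc.add(float(t))
    return acc.value


def site_loglik_fast(
    site: SiteObservations,
    params: NMixParams,
    variant,
    bound: TruncationBound,
) -> float:
    """Incremental-ratio site log-likelihood.

    Evaluates the full pmfs only at N0 = max(y); every later term is the
    previous one plus the abundance log ratio and J detection log ratios,
    accumulated in a streaming log-sum.
    """
    variant = _as_variant(variant)
    ymax = int(site.counts.max())
    if bound.K < ymax:
        raise ValueError(f"K={bound.K} is below max observed count {ymax}")
    lam_i, p_ij = _site_linear_predictors(site, params)
    ab, det = _dists_for(variant, lam_i, p_ij, params.theta_w, params.theta_b)

    log_term = abundance_log_pmf(ab, ymax) + sum(
        detection_log_pmf(d, int(yj), ymax)
        for d, yj in zip(det, site.counts)
    )
    acc = StreamLogSum()
    acc.add(log_term)
    for n in range(ymax, bound.K):
        log_term += abundance_log_ratio(ab, n)
        for d, yj in zip(det, site.counts):
            log_term += detection_log_ratio(d, int(yj), n)
        acc.add(log_term)
    return acc.value


class PackedNMixData:
    """Sites grouped by number of visits for batched likelihood evaluation.

    Packing once and reusing across optimizer iterations keeps a dataset
    evaluation to a few large array operations per visit-count group.
    """

    def __init__(self, data: list[SiteObservations]):
        if not data:
            raise ValueError("empty dataset")
        groups: dict[int, list[int]] = {}
        for i, s in enumerate(data):
            groups.setdefault(s.n_visits, []).append(i)
        self.groups = []
        for j, idx in sorted(groups.items()):
            y = np.stack([data[i].counts for i in idx])
            xw = np.stack([data[i].detection_design for i in idx])
            xb = np.stack([data[i].abundance_covariates for i in idx])
            self.groups.append((j, np.asarray(idx), y, xw, xb))
        self.max_count = max(int(g[2].max()) for g in self.groups)
        self.n_sites = len(data)
        self.n_obs = sum(s.n_visits for s in data)

    def loglik(
        self,
        params: NMixParams,
        variant,
        bound: TruncationBound,
        backend: str = "fast",
    ) -> float:
        if backend not in ("fast", "naive"):
            raise ValueError("backend must be 'fast' or 'naive'")
        variant = _as_variant(variant)
        if self.max_count > bound.K:
            raise ValueError("K below max observed count")
        if variant.has_theta_w != (params.theta_w is not None):
            raise ValueError("theta_w presence must match the variant")
        if variant.has_theta_b != (params.theta_b is not None):
            raise ValueError("theta_b presence must match the variant")
        lam0, p0 = intercepts_from_phi(params.phi1, params.phi2)
        kernel = _fast_kernel if backend == "fast" else _batch_loglik_naive
        total = 0.0
        for j, idx, y, xw, xb in self.groups:
            if xw.shape[2] != params.beta_w.size:
                raise ValueError("detection design / beta_w dimension mismatch")
            if xb.shape[1] != params.beta_b.size:
                raise ValueError(
                    "abundance covariates / beta_b dimension mismatch"
                )
            p = np.clip(
                expit(logit(p0) + xw @ params.beta_w), 1e-12, 1.0 - 1e-12
            )
            lam = np.exp(np.log(lam0) + xb @ params.beta_b)
            if not (np.all(np.isfinite(p)) and np.all(np.isfinite(lam))):
                raise ValueError("non-finite linear predictor")
            total += float(
                np.sum(
                    kernel(
                        y, p, lam, variant, params.theta_w, params.theta_b,
                        bound.K,
                    )
                )
            )
        return total


def dataset_loglik(
    params: NMixParams,
    data: list[SiteObservations],
    variant,
    bound: TruncationBound | None = None,
    backend: str = "fast",
) -> float:
    """Dataset log-likelihood: covariate links applied, sites summed.

    logit(p_ij) = logit(p0) + x_ij(w) beta_w per visit;
    log(lambda_i) = log(lambda0) + x_i(b) beta_b per site.
    """
    if bound is None:
        bound = default_truncation(np.concatenate([s.counts for s in data]))
    return PackedNMixData(data).loglik(params, variant, bound, backend)


def benchmark_backends(
    K_values=(100, 500, 2000),
    visit_counts=(5, 20),
    variants=("B-P", "B-NB", "BB-P", "BB-NB"),
    n_sites: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Time both backends on simulated sites across a (K, J, variant) grid.

    Returns a tidy table with one row per cell and backend; the
    ``max_abs_diff`` column is the largest per-site absolute discrepancy
    between the two backends in that cell.
    """
    rows = []
    for variant_name in variants:
        variant = _as_variant(variant_name)
        for K in K_values:
            for J in visit_counts:
                rng = np.random.default_rng(seed)
                params = NMixParams(
                    phi1=0.5,
                    phi2=-2.0,
                    theta_w=2.0 if variant.has_theta_w else None,
                    theta_b=1.5 if variant.has_theta_b else None,
                )
                lam0, p0 = intercepts_from_phi(params.phi1, params.phi2)
                n_latent = rng.poisson(lam0, size=n_sites)
                y = rng.binomial(n_latent[:, None], p0, size=(n_sites, J))
                data = [SiteObservations(counts=y[i]) for i in range(n_sites)]
                bound = TruncationBound(K)
                per_site = {}
                for backend in ("naive", "fast"):
                    kernel = (
                        _batch_loglik_fast
                        if backend == "fast"
                        else _batch_loglik_naive
                    )
                    p = np.full((n_sites, J), p0)
                    lam = np.full(n_sites, lam0)
                    t0 = time.perf_counter()
                    vals = kernel(
                        y, p, lam, variant, params.theta_w, params.theta_b, K
                    )
                    dt = time.perf_counter() - t0
                    per_site[backend] = vals
                    rows.append(
                        {
                            "variant": variant.name,
                            "K": K,
                            "n_visits": J,
                            "n_sites": n_sites,
                            "backend": backend,
                            "seconds": dt,
                        }
                    )
                diff = float(
                    np.max(np.abs(per_site["fast"] - per_site["naive"]))
                )
                rows[-1]["max_abs_diff"] = diff
                rows[-2]["max_abs_diff"] = diff
    return pd.DataFrame(rows)
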