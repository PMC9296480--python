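"""N-mixture marginal likelihood: rotation, backends, truncation."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from relabund.nmixture_likelihood import (
    VARIANTS,
    NMixParams,
    SiteObservations,
    TruncationBound,
    benchmark_backends,
    dataset_loglik,
    default_truncation,
    intercepts_from_phi,
    phi_from_intercepts,
    site_loglik_fast,
    site_loglik_naive,
)


def brute_force_site_loglik(y, p, lam, K, theta_w=None, theta_b=None):
    """Independent truncated-sum oracle built directly on scipy pmfs."""
    n = np.arange(0, K + 1)
    if theta_b is None:
        ab = stats.poisson.logpmf(n, lam)
    else:
        ab = stats.nbinom.logpmf(n, theta_b, theta_b / (theta_b + lam))
    det = np.zeros(n.size)
    for j, yj in enumerate(np.atleast_1d(y)):
        pj = p if np.isscalar(p) else p[j]
        if theta_w is None:
            det += stats.binom.logpmf(yj, n, pj)
        else:
            det += stats.betabinom.logpmf(
                yj, n, pj * theta_w, (1 - pj) * theta_w
            )
    return float(logsumexp(ab + det))


def draw_case(rng, j_max=20, k_range=(100, 2000)):
    name = rng.choice(list(VARIANTS))
    variant = VARIANTS[name]
    J = int(rng.integers(1, j_max + 1))
    K = int(rng.integers(*k_range))
    phi1 = rng.normal(0, 1)
    phi2 = -abs(rng.normal(2, 1)) - abs(phi1)
    params = NMixParams(
        phi1,
        phi2,
        theta_w=rng.uniform(0.5, 5) if variant.has_theta_w else None,
        theta_b=rng.uniform(0.5, 5) if variant.has_theta_b else None,
    )
    lam0, p0 = intercepts_from_phi(phi1, phi2)
    y = rng.binomial(rng.poisson(3 * lam0), p0, size=J)
    return name, params, SiteObservations(counts=y), TruncationBound(K)


class TestInterceptRotation:
    @pytest.mark.parametrize(
        "phi1, phi2, lam0, p0",
        [
            (-1.0, -1.0, 1.0, math.exp(-1.0)),
            (0.0, -2.0, math.e, math.exp(-1.0)),
        ],
    )
    def test_forward_map(self, phi1, phi2, lam0, p0):
        out = intercepts_from_phi(phi1, phi2)
        assert out[0] == pytest.approx(lam0, rel=1e-14)
        assert out[1] == pytest.approx(p0, rel=1e-14)
        # defining identities hold exactly
        assert out[0] * out[1] == pytest.approx(math.exp(phi1), rel=1e-14)
        assert out[1] / out[0] == pytest.approx(math.exp(phi2), rel=1e-14)

    def test_round_trip(self):
        phi1, phi2 = phi_from_intercepts(4.7, 0.23)
        lam0, p0 = intercepts_from_phi(phi1, phi2)
        assert lam0 == pytest.approx(4.7, abs=1e-14)
        assert p0 == pytest.approx(0.23, abs=1e-14)

    def test_invalid_region(self):
        with pytest.raises(ValueError):
            intercepts_from_phi(1.0, -0.5)
        with pytest.raises(ValueError):
            phi_from_intercepts(2.0, 1.0)

    def test_likelihood_invariant_under_round_trip(self):
        rng = np.random.default_rng(5)
        name, params, site, bound = draw_case(rng, j_max=5, k_range=(100, 300))
        p1, p2 = phi_from_intercepts(
            *intercepts_from_phi(params.phi1, params.phi2)
        )
        again = NMixParams(
            p1, p2, theta_w=params.theta_w, theta_b=params.theta_b
        )
        a = dataset_loglik(params, [site], name, bound)
        b = dataset_loglik(again, [site], name, bound)
        assert a == b  # bit-identical


class TestSiteLoglik:
    def test_single_visit_thinning(self):
        # one visit: B-P marginal is exactly Poisson(lam * p)
        params = NMixParams(*phi_from_intercepts(4.0, 0.5))
        site = SiteObservations(counts=[2])
        val = site_loglik_naive(site, params, "B-P", TruncationBound(200))
        assert val == pytest.approx(stats.poisson.logpmf(2, 2.0), abs=1e-10)

    def test_bp_two_visits_frozen_value(self):
        # independently computed truncated sum: P(y = (1,0)) = 0.1180916...
        params = NMixParams(*phi_from_intercepts(1.0, 0.5))
        site = SiteObservations(counts=[1, 0])
        val = site_loglik_naive(site, params, "B-P", TruncationBound(100))
        assert val == pytest.approx(math.log(0.11809163818525366), abs=1e-10)
        assert val == pytest.approx(
            brute_force_site_loglik([1, 0], 0.5, 1.0, 100), abs=1e-12
        )

    def test_bbnb_matches_brute_force(self):
        params = NMixParams(
            *phi_from_intercepts(1.0, 0.5), theta_w=2.0, theta_b=1.0
        )
        site = SiteObservations(counts=[1, 0])
        oracle = brute_force_site_loglik(
            [1, 0], 0.5, 1.0, 100, theta_w=2.0, theta_b=1.0
        )
        for fn in (site_loglik_naive, site_loglik_fast):
            assert fn(site, params, "BB-NB", TruncationBound(100)) == (
                pytest.approx(oracle, abs=1e-10)
            )

    def test_k_below_max_count_rejected(self):
        params = NMixParams(*phi_from_intercepts(4.0, 0.5))
        site = SiteObservations(counts=[7])
        with pytest.raises(ValueError):
            site_loglik_naive(site, params, "B-P", TruncationBound(5))

    def test_fast_equals_naive_randomized(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(150):
            name, params, site, bound = draw_case(rng, k_range=(100, 800))
            naive = site_loglik_naive(site, params, name, bound)
            fast = site_loglik_fast(site, params, name, bound)
            batch = dataset_loglik(params, [site], name, bound, "fast")
            worst = max(worst, abs(naive - fast), abs(naive - batch))
        assert worst < 1e-8

    def test_k_convergence(self):
        # once the tail is negligible, increasing K cannot move the value
        params = NMixParams(*phi_from_intercepts(5.0, 0.3))
        site = SiteObservations(counts=[3, 1, 2])
        vals = [
            site_loglik_fast(site, params, "B-P", TruncationBound(K))
            for K in (60, 160, 400, 500)
        ]
        assert vals[1] >= vals[0] - 1e-14  # nondecreasing in K
        assert abs(vals[3] - vals[2]) < 1e-10
        assert abs(vals[2] - vals[1]) <= abs(vals[1] - vals[0]) + 1e-12


class TestDatasetLoglik:
    def test_matches_single_site(self):
        rng = np.random.default_rng(2)
        name, params, site, bound = draw_case(rng, j_max=4, k_range=(100, 200))
        assert dataset_loglik(params, [site], name, bound) == pytest.approx(
            site_loglik_naive(site, params, name, bound), abs=1e-8
        )

    def test_additive_over_sites(self):
        rng = np.random.default_rng(3)
        params = NMixParams(0.5, -2.0)
        sites = [
            SiteObservations(counts=rng.poisson(2, size=3)) for _ in range(2)
        ]
        bound = TruncationBound(300)
        joint = dataset_loglik(params, sites, "B-P", bound)
        parts = sum(
            dataset_loglik(params, [s], "B-P", bound) for s in sites
        )
        assert joint == pytest.approx(parts, abs=1e-12)

    def test_covariate_links(self):
        # beta = 0 must reduce to the shared-intercept likelihood
        rng = np.random.default_rng(4)
        y = rng.poisson(2, size=4)
        plain = SiteObservations(counts=y)
        with_x = SiteObservations(
            counts=y,
            detection_design=rng.normal(size=(4, 2)),
            abundance_covariates=rng.normal(size=3),
        )
        params0 = NMixParams(0.5, -2.0)
        paramsx = NMixParams(
            0.5, -2.0, beta_w=np.zeros(2), beta_b=np.zeros(3)
        )
        bound = TruncationBound(300)
        assert dataset_loglik(paramsx, [with_x], "B-P", bound) == (
            pytest.approx(dataset_loglik(params0, [plain], "B-P", bound),
                          abs=1e-12)
        )

    def test_dimension_mismatch(self):
        site = SiteObservations(counts=[1], detection_design=[[1.0, 2.0]])
        params = NMixParams(0.5, -2.0, beta_w=[0.1])
        with pytest.raises(ValueError):
            dataset_loglik(params, [site], "B-P", TruncationBound(100))

    def test_default_truncation_rule(self):
        assert default_truncation([3]).K == 1000
        assert default_truncation([80]).K == 1600


class TestThinningIdentities:
    def test_bp_equals_poisson(self):
        lam0, p0 = 6.0, 0.4
        params = NMixParams(*phi_from_intercepts(lam0, p0))
        for y in (0, 2, 7):
            got = site_loglik_fast(
                SiteObservations(counts=[y]), params, "B-P",
                TruncationBound(400),
            )
            assert got == pytest.approx(
                stats.poisson.logpmf(y, lam0 * p0), abs=1e-8
            )

    def test_bnb_equals_negbinom(self):
        lam0, p0, tb = 6.0, 0.4, 1.5
        params = NMixParams(*phi_from_intercepts(lam0, p0), theta_b=tb)
        mean = lam0 * p0
        for y in (0, 2, 7):
            got = site_loglik_fast(
                SiteObservations(counts=[y]), params, "B-NB",
                TruncationBound(800),
            )
            want = stats.nbinom.logpmf(y, tb, tb / (tb + mean))
            assert got == pytest.approx(want, abs=1e-8)


class TestBenchmark:
    def test_single_cell_table(self):
        t = benchmark_backends(
            K_values=(100,), visit_counts=(5,), variants=("B-P",),
            n_sites=10, seed=1,
        )
        assert len(t) == 2  # one row per backend
        assert (t.seconds > 0).all()
        assert (t.max_abs_diff < 1e-8).all()

    def test_deterministic_given_seed(self):
        a = benchmark_backends(
            K_values=(100,), visit_counts=(5,), variants=("BB-P",),
            n_sites=10, seed=3,
        )
        b = benchmark_backends(
            K_values=(100,), visit_counts=(5,), variants=("BB-P",),
            n_sites=10, seed=3,
        )
        assert (a.max_abs_diff == b.max_abs_diff).all()
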