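"""Design preparation, MLE fitting, forward selection, ranking."""

import numpy as np
import pandas as pd
import pytest

from relabund.glmm_likelihood import GLMMParams
from relabund.model_fitting import (
    FitOptions,
    ModelSpec,
    base_spec,
    comparable_estimates,
    default_candidate_terms,
    fit_model,
    forward_aic_select,
    prepare_design,
    rank_models,
)
from relabund.synthetic_data import (
    ScenarioConfig,
    generate_design,
    make_fixture,
    simulate_counts,
)


class TestPrepareDesign:
    def test_constant_covariate_dropped(self, toy_checklists, toy_sites):
        sites = toy_sites.copy()
        sites["elevation"] = 1.5
        bundle = prepare_design(toy_checklists, sites)
        assert "elevation" not in bundle.term_level
        assert ("elevation", "single unique value") in bundle.dropped

    def test_collinear_interaction_dropped(self, toy_checklists, toy_sites):
        # raw products (0.02, 0.08, 0.18, 0.36) correlate ~0.97 with the
        # first-order fractions (0.1, 0.2, 0.3, 0.4)
        bundle = prepare_design(toy_checklists, toy_sites)
        dropped_names = [d[0] for d in bundle.dropped]
        assert "pct_water:pct_trees" in dropped_names
        assert "pct_water:pct_trees" not in bundle.interactions

    def test_centering(self, toy_checklists, toy_sites):
        bundle = prepare_design(toy_checklists, toy_sites)
        for name in ("elevation", "duration_minutes"):
            col = bundle.obs_cols[name]
            # site-level columns are centered over sites, not checklists
            ref = (
                bundle.site_cols[name]
                if name in bundle.site_cols
                else col
            )
            assert abs(ref.mean()) < 1e-12
        info = bundle.centering_info["duration_minutes"]
        raw = toy_checklists.duration_minutes.to_numpy()
        assert info[0] == pytest.approx(raw.mean())

    def test_quadratic_terms_built(self, toy_checklists, toy_sites):
        bundle = prepare_design(toy_checklists, toy_sites)
        assert bundle.quadratic_of["time_of_day_sq"] == "time_of_day"
        assert "julian_date_sq" in bundle.term_level

    def test_missing_columns_reported(self, toy_checklists, toy_sites):
        with pytest.raises(ValueError, match="elevation"):
            prepare_design(toy_checklists, toy_sites.drop(columns="elevation"))


class TestFitModel:
    def test_aic_identity(self, tiny_bundle):
        fx, bundle = tiny_bundle
        fit = fit_model(fx["spec"], bundle, FitOptions(K=1000))
        assert fit.aic == pytest.approx(
            -2 * fit.loglik + 2 * fit.n_params, abs=0.0
        )
        assert fit.K_used == 1000

    def test_poisson_glm_slope_recovery(self):
        # generating sigma_alpha = 0: plain GLM; slope within 3 SE of truth
        cfg = ScenarioConfig(n_sites=500, visit_mean=10.0,
                             hotspot_fraction=0.0, seed=21)
        spec = ModelSpec.glmm("poisson", terms=("elevation",))
        params = GLMMParams(beta0=0.5, beta=[0.4], sigma_alpha=0.0)
        design = generate_design(cfg)
        checklists, _ = simulate_counts(design, spec, params, seed=22)
        bundle = prepare_design(checklists, design[0], standardize=False)
        fit = fit_model(spec, bundle)
        assert fit.converged
        se = fit.std_errors["elevation"]
        assert abs(fit.estimates["elevation"] - 0.4) < 3 * se
        assert fit.estimates["sigma_alpha"] < 0.1

    def test_single_visit_ridge_flagged(self):
        # J = 1 leaves phi2 unidentified (thinning); the flat direction
        # must surface as a singular Hessian or a boundary flag
        fx = make_fixture("ridge_j1", seed=2)
        bundle = prepare_design(fx["checklists"], fx["sites"])
        fit = fit_model(fx["spec"], bundle, FitOptions(K=1000))
        ridge_detected = (
            fit.flags.get("singular_hessian", False)
            or fit.boundary_phi2
            or fit.std_errors.get("phi2") is None
            or fit.std_errors.get("phi2", 0.0) > 10.0
        )
        assert ridge_detected

    def test_multistart_agreement(self, tiny_bundle):
        fx, bundle = tiny_bundle
        a = fit_model(fx["spec"], bundle, FitOptions(K=1000))
        start = np.array([0.0, -1.0, 0.0, 0.0])
        b = fit_model(fx["spec"], bundle, FitOptions(K=1000, start=start))
        assert a.loglik == pytest.approx(b.loglik, abs=1e-4)

    def test_checklist_term_rejected_in_abundance(self, tiny_bundle):
        _, bundle = tiny_bundle
        bad = ModelSpec.nmixture(
            "B-P", abundance_terms=("duration_minutes",)
        )
        with pytest.raises(ValueError):
            fit_model(bad, bundle, FitOptions(K=500))

    def test_glmm_fit_recovers_dispersion(self):
        fx = make_fixture("glmm_nb", seed=31)
        bundle = prepare_design(fx["checklists"], fx["sites"])
        fit = fit_model(fx["spec"], bundle)
        assert fit.converged
        assert 0.5 < fit.estimates["theta"] < 5.0
        assert 0.4 < fit.estimates["sigma_alpha"] < 1.4


class TestForwardSelection:
    def test_empty_candidates_returns_base(self, tiny_bundle):
        fx, bundle = tiny_bundle
        base = base_spec("nmixture", "B-P", bundle)
        trace, best = forward_aic_select(base, (), bundle, FitOptions(K=800))
        assert best.spec == base
        assert trace.steps == []

    def test_strong_covariate_enters(self):
        # elevation effect 1.0 on log abundance; selection must find it
        hits = 0
        for rep in range(5):
            cfg = ScenarioConfig(n_sites=150, visit_mean=4.0,
                                 hotspot_fraction=0.0, seed=400 + rep)
            gen_spec = ModelSpec.nmixture(
                "B-P", abundance_terms=("pct_trees",)
            )
            from relabund.nmixture_likelihood import NMixParams

            params = NMixParams(0.5, -2.0, beta_b=[1.0])
            design = generate_design(cfg)
            checklists, _ = simulate_counts(design, gen_spec, params,
                                            seed=500 + rep)
            bundle = prepare_design(checklists, design[0])
            base = ModelSpec.nmixture("B-P")
            trace, best = forward_aic_select(
                base, ("pct_trees",), bundle, FitOptions(K=800)
            )
            if "pct_trees" in (
                best.spec.abundance_terms + best.spec.detection_terms
            ):
                hits += 1
        assert hits >= 4

    def test_accepted_aic_sequence_decreases(self, tiny_bundle):
        fx, bundle = tiny_bundle
        base = base_spec("nmixture", "B-P", bundle)
        trace, best = forward_aic_select(
            base, ("pct_trees", "pct_water"), bundle, FitOptions(K=800)
        )
        accepted = [s["aic"] for s in trace.steps if s.get("accepted")]
        assert all(b < a for a, b in zip(accepted, accepted[1:]))
        for s in trace.steps:  # a priori terms never removed
            assert set(base.detection_terms) <= set(best.spec.detection_terms)
            assert set(base.abundance_terms) <= set(best.spec.abundance_terms)

    def test_quadratic_requires_linear(self, tiny_bundle):
        _, bundle = tiny_bundle
        base = ModelSpec.nmixture("B-P")
        from relabund.model_fitting import _admissible_moves

        moves = _admissible_moves(
            base, ("time_of_day_sq", "time_of_day"), bundle
        )
        assert ("time_of_day_sq", "detection") not in moves
        assert ("time_of_day", "detection") in moves

    def test_checklist_terms_only_in_detection(self, tiny_bundle):
        _, bundle = tiny_bundle
        from relabund.model_fitting import _admissible_moves

        moves = _admissible_moves(
            ModelSpec.nmixture("B-P"), ("julian_date", "pct_trees"), bundle
        )
        assert ("julian_date", "abundance") not in moves
        assert ("pct_trees", "abundance") in moves
        assert ("pct_trees", "detection") in moves


def _stub_fit(label, aic, n_params=3, n_obs=100):
    from relabund.model_fitting import FitResult

    family, dist = label.split(":")
    spec = (
        ModelSpec.glmm(dist)
        if family == "glmm"
        else ModelSpec.nmixture(dist)
    )
    return FitResult(
        spec=spec, estimates={}, std_errors={}, loglik=-(aic - 2 * n_params) / 2,
        n_params=n_params, aic=aic, K_used=None, converged=True,
        boundary_phi2=False, flags={}, centering_info={}, n_obs=n_obs,
        n_sites=10,
    )


class TestRankModels:
    def test_clear_support_threshold(self):
        r = rank_models(
            [_stub_fit("glmm:poisson", 103.0), _stub_fit("nmixture:B-P", 100.0)]
        )
        assert r.best_label == "nmixture:B-P"
        assert r.table.iloc[1].clearly_worse_than_best
        assert r.contrast["clearly_supported"] == "nmixture"

    def test_no_clear_support_within_two(self):
        r = rank_models(
            [_stub_fit("glmm:poisson", 101.0), _stub_fit("nmixture:B-P", 100.0)]
        )
        assert not r.table.iloc[1].clearly_worse_than_best
        assert r.contrast["clearly_supported"] is None

    def test_ties_broken_by_fewer_params(self):
        a = _stub_fit("glmm:poisson", 100.0, n_params=5)
        b = _stub_fit("glmm:negbinom", 100.0, n_params=3)
        r = rank_models([a, b])
        assert r.best_label == "glmm:negbinom"

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError):
            rank_models(
                [_stub_fit("glmm:poisson", 1.0, n_obs=50),
                 _stub_fit("glmm:negbinom", 2.0, n_obs=60)]
            )


class TestComparableEstimates:
    def test_glmm_lognormal_adjustment(self):
        fit = _stub_fit("glmm:poisson", 100.0)
        fit.estimates = {"beta0": 1.0, "sigma_alpha": 0.5}
        fit.std_errors = {"beta0": 0.1, "sigma_alpha": 0.05}
        out = comparable_estimates(fit)
        assert out["log_expected_count"] == pytest.approx(1.125)

    def test_nmixture_returns_phi1(self):
        fit = _stub_fit("nmixture:B-P", 100.0)
        fit.estimates = {"phi1": 0.42, "phi2": -2.0}
        fit.std_errors = {"phi1": 0.07, "phi2": 0.2}
        out = comparable_estimates(fit)
        assert out["log_expected_count"] == 0.42
        assert out["log_expected_count_se"] == 0.07

    def test_delta_method_matches_closed_form(self):
        fit = _stub_fit("glmm:poisson", 100.0)
        sigma = 0.6
        fit.estimates = {"beta0": 1.0, "sigma_alpha": sigma}
        fit.internal_names = ("beta0", "log_sigma_alpha")
        cov = np.array([[0.04, 0.002], [0.002, 0.09]])
        fit.cov_internal = cov
        out = comparable_estimates(fit)
        # on the internal (log sigma) scale: d g / d log sigma = sigma^2
        want = np.sqrt(
            cov[0, 0] + sigma**4 * cov[1, 1] + 2 * sigma**2 * cov[0, 1]
        )
        assert out["log_expected_count_se"] == pytest.approx(want, rel=1e-12)


class TestDefaultCandidates:
    def test_pool_contents(self, tiny_bundle):
        _, bundle = tiny_bundle
        pool = default_candidate_terms(bundle)
        assert "pct_trees" in pool
        assert "time_of_day_sq" in pool
        assert "elevation" not in pool  # a priori, never a candidate
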