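"""Synthetic checklist-style datasets with known truth.

Emulates the structure of filtered citizen-science point-count data: sites
on a planar 50 m grid with habitat covariates (elevation, compositional
land-cover fractions), replicate checklists per site with effort covariates
(duration, observers, time of day, date), and counts generated from any of
the six models (four N-mixture variants or a Poisson/negative-binomial
GLMM).  Visit counts are clustered: a small fraction of "hotspot" sites
carries many replicate checklists, the rest few, mirroring how birding
activity concentrates at popular locations.

All randomness flows through a single integer seed, so every table and
every latent truth value is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .nmixture_likelihood import (
    VARIANTS,
    NMixParams,
    intercepts_from_phi,
)
from .glmm_likelihood import GLMMParams

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "generate_design",
    "simulate_counts",
    "make_fixture",
    "PRESETS",
]

LAND_COVER_COLUMNS = (
    "pct_water",
    "pct_trees",
    "pct_agriculture",
    "pct_other_vegetation",
)


@dataclass
class ScenarioConfig:
    """Study-condition knobs for one synthetic species-subregion dataset.

    Visit clustering: ``hotspot_fraction`` of sites draw their number of
    checklists as 1 + Poisson(hotspot_visit_mean); the rest use
    1 + Poisson(visit_mean).  Durations are log-normal minutes truncated to
    the quality-filter window (< 240 min); observers are 1 + Poisson capped
    at 10; land cover is Dirichlet-compositional with an unmodeled "bare"
    remainder so the four stored fractions sum to <= 1.
    """

    n_sites: int = 100
    visit_mean: float = 2.0
    hotspot_fraction: float = 0.15
    hotspot_visit_mean: float = 20.0
    region_size_m: float = 20000.0
    cell_size_m: float = 50.0
    elevation_sd: float = 1.0
    landcover_alpha: tuple = (2.0, 4.0, 1.5, 2.5, 2.0)  # last = bare remainder
    duration_log_mean: float = np.log(60.0)
    duration_log_sd: float = 0.5
    observers_rate: float = 0.6
    time_range: tuple = (5.0, 20.0)
    date_range: tuple = (91, 181)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ValueError("hotspot_fraction must lie in [0, 1]")
        if len(self.landcover_alpha) != 5:
            raise ValueError(
                "landcover_alpha needs 5 entries (4 stored classes + remainder)"
            )


@dataclass
class SyntheticTruth:
    """Latent quantities behind a simulated dataset."""

    model_family: str
    params: Any
    latent_abundance: np.ndarray | None = None  # N_i, n-mixture path
    site_lambda: np.ndarray | None = None  # lambda_i
    detection_prob: pd.Series | None = None  # p_ij per checklist
    random_effects: np.ndarray | None = None  # alpha_i, glmm path
    mu: pd.Series | None = None  # mu_ij per checklist
    covariate_effects: dict = field(default_factory=dict)


def generate_design(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the site table and the (count-free) checklist table.

    Sites occupy distinct cells of the planar grid; each checklist gets
    coordinates jittered within its site's cell plus effort covariates.
    """
    rng = np.random.default_rng(config.seed)
    n_cells = int(config.region_size_m // config.cell_size_m)
    if config.n_sites > n_cells**2:
        raise ValueError("more sites than grid cells in the region")

    # distinct grid cells
    flat = rng.choice(n_cells**2, size=config.n_sites, replace=False)
    cx, cy = flat // n_cells, flat % n_cells
    site_ids = [f"{a}_{b}" for a, b in zip(cx, cy)]

    lc = rng.dirichlet(config.landcover_alpha, size=config.n_sites)
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "x": (cx + 0.5) * config.cell_size_m,
            "y": (cy + 0.5) * config.cell_size_m,
            "elevation": rng.normal(0.0, config.elevation_sd, config.n_sites),
        }
    )
    for k, col in enumerate(LAND_COVER_COLUMNS):
        sites[col] = lc[:, k]

    hot = rng.random(config.n_sites) < config.hotspot_fraction
    means = np.where(hot, config.hotspot_visit_mean, config.visit_mean)
    n_visits = 1 + rng.poisson(np.maximum(means - 1.0, 0.0))

    rows = []
    cid = 0
    for i in range(config.n_sites):
        for _ in range(int(n_visits[i])):
            dur = float(
                np.exp(
                    rng.normal(config.duration_log_mean, config.duration_log_sd)
                )
            )
            dur = min(max(dur, 5.0), 239.0)
            rows.append(
                {
                    "checklist_id": f"C{cid:06d}",
                    "site_id": site_ids[i],
                    "x": sites.x[i] + rng.uniform(-20, 20),
                    "y": sites.y[i] + rng.uniform(-20, 20),
                    "duration_minutes": dur,
                    "n_observers": int(min(1 + rng.poisson(config.observers_rate), 10)),
                    "time_of_day": float(rng.uniform(*config.time_range)),
                    "julian_date": int(rng.integers(config.date_range[0], config.date_range[1] + 1)),
                    "protocol": "stationary",
                    "complete": True,
                }
            )
            cid += 1
    checklists = pd.DataFrame(rows)
    return sites, checklists


SITE_LEVEL_COLUMNS = ("elevation",) + LAND_COVER_COLUMNS


def _standardized(series: pd.Series) -> np.ndarray:
    v = series.to_numpy(dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _effect_eta(
    merged: pd.DataFrame,
    sites: pd.DataFrame,
    obs_site: np.ndarray,
    effects: dict[str, float],
) -> np.ndarray:
    """Per-checklist linear predictor contribution from covariate effects.

    Effects act on standardized covariates; site-level covariates are
    standardized over the site table (one value per site) and broadcast to
    checklists, checklist-level covariates over the checklist rows.  The
    fitting layer applies the same convention, so generating coefficients
    are directly comparable to estimates.
    """
    eta = np.zeros(len(merged))
    for name, coef in effects.items():
        if name in SITE_LEVEL_COLUMNS:
            eta += coef * _standardized(sites[name])[obs_site]
        else:
            eta += coef * _standardized(merged[name])
    return eta


def simulate_counts(
    design: tuple[pd.DataFrame, pd.DataFrame],
    spec,
    params,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw counts for every checklist under one of the six models.

    ``spec`` is a :class:`~relabund.model_fitting.ModelSpec` (or anything
    with the same ``family`` / distribution fields).  For N-mixture specs
    ``params`` is an :class:`NMixParams`; for GLMMs a :class:`GLMMParams`.
    Detection/abundance (or GLMM) covariate effects are read from the
    spec's term lists paired with the coefficient vectors in ``params``.
    """
    sites, checklists = design
    rng = np.random.default_rng(seed)
    out = checklists.copy()
    merged = out.join(
        sites.set_index("site_id"), on="site_id", rsuffix="_site"
    )  # preserves checklist row order
    site_order = sites.site_id.tolist()
    site_pos = {s: k for k, s in enumerate(site_order)}
    obs_site = out.site_id.map(site_pos).to_numpy()

    if spec.family == "nmixture":
        if not isinstance(params, NMixParams):
            raise ValueError("nmixture spec requires NMixParams")
        variant = VARIANTS[spec.variant]
        lam0, p0 = intercepts_from_phi(params.phi1, params.phi2)
        site_effects = dict(zip(spec.abundance_terms, params.beta_b))
        eta_b = np.log(lam0)
        for name, coef in site_effects.items():
            eta_b = eta_b + coef * _standardized(sites[name])
        lam = np.exp(np.broadcast_to(eta_b, (len(sites),)).astype(float))
        eta_w = logit(p0) + _effect_eta(
            merged, sites, obs_site, dict(zip(spec.detection_terms, params.beta_w))
        )
        p = expit(eta_w)

        if variant.between == "poisson":
            n_latent = rng.poisson(lam)
        else:
            th = params.theta_b
            n_latent = rng.negative_binomial(th, th / (th + lam))
        if variant.within == "binomial":
            y = rng.binomial(n_latent[obs_site], p)
        else:
            tw = params.theta_w
            pp = rng.beta(p * tw, (1.0 - p) * tw)
            y = rng.binomial(n_latent[obs_site], pp)
        out["count"] = y.astype(np.int64)
        truth = SyntheticTruth(
            model_family="nmixture",
            params=params,
            latent_abundance=n_latent,
            site_lambda=lam,
            detection_prob=pd.Series(p, index=out.checklist_id),
            covariate_effects={
                "detection": dict(zip(spec.detection_terms, params.beta_w)),
                "abundance": dict(zip(spec.abundance_terms, params.beta_b)),
            },
        )
    elif spec.family == "glmm":
        if not isinstance(params, GLMMParams):
            raise ValueError("glmm spec requires GLMMParams")
        alpha = rng.normal(0.0, params.sigma_alpha, size=len(sites))
        eta = (
            params.beta0
            + _effect_eta(merged, sites, obs_site, dict(zip(spec.terms, params.beta)))
            + alpha[obs_site]
        )
        mu = np.exp(eta)
        if spec.count_dist == "poisson":
            y = rng.poisson(mu)
        else:
            th = params.theta
            y = rng.negative_binomial(th, th / (th + mu))
        out["count"] = y.astype(np.int64)
        truth = SyntheticTruth(
            model_family="glmm",
            params=params,
            random_effects=alpha,
            mu=pd.Series(mu, index=out.checklist_id),
            covariate_effects={"terms": dict(zip(spec.terms, params.beta))},
        )
    else:
        raise ValueError(f"unknown model family {spec.family!r}")
    return out, truth


def _preset_specs():
    # local import: model_fitting depends on this module's tables otherwise
    from .model_fitting import ModelSpec

    return {
        "well_identified_bp": dict(
            config=ScenarioConfig(
                n_sites=150, visit_mean=5.0, hotspot_fraction=0.0
            ),
            spec=ModelSpec.nmixture(
                "B-P",
                detection_terms=("duration_minutes",),
                abundance_terms=("elevation",),
            ),
            params=NMixParams(
                phi1=0.5, phi2=-2.0, beta_w=[-0.5], beta_b=[0.5]
            ),
            options=dict(K=1000),
        ),
        "overdispersed_bbp": dict(
            config=ScenarioConfig(
                n_sites=100, visit_mean=5.0, hotspot_fraction=0.0
            ),
            spec=ModelSpec.nmixture("BB-P"),
            params=NMixParams(phi1=1.0, phi2=-1.5, theta_w=2.0),
            options=dict(K=1000),
        ),
        "ridge_j1": dict(
            config=ScenarioConfig(
                n_sites=100, visit_mean=1.0, hotspot_fraction=0.0
            ),
            spec=ModelSpec.nmixture("B-P"),
            params=NMixParams(phi1=0.5, phi2=-2.0),
            options=dict(K=1000),
        ),
        "glmm_nb": dict(
            config=ScenarioConfig(
                n_sites=100, visit_mean=4.0, hotspot_fraction=0.1
            ),
            spec=ModelSpec.glmm("negbinom", terms=("elevation",)),
            params=GLMMParams(
                beta0=1.0, beta=[0.5], sigma_alpha=0.8, theta=1.5
            ),
            options=dict(),
        ),
        # residual-calibration scenarios: small, weak-dependence designs
        # where the KS independence assumptions hold to good approximation
        "bp_gof_calibration": dict(
            config=ScenarioConfig(
                n_sites=60, visit_mean=3.0, hotspot_fraction=0.0
            ),
            spec=ModelSpec.nmixture("B-P"),
            params=NMixParams(phi1=0.5, phi2=-2.0),
            options=dict(K=1000),
        ),
        "glmm_gof_calibration": dict(
            config=ScenarioConfig(
                n_sites=100, visit_mean=1.0, hotspot_fraction=0.0
            ),
            spec=ModelSpec.glmm("poisson"),
            params=GLMMParams(beta0=0.5, sigma_alpha=0.3),
            options=dict(),
        ),
        "tiny_toy": dict(
            config=ScenarioConfig(
                n_sites=3, visit_mean=2.0, hotspot_fraction=0.0
            ),
            spec=ModelSpec.nmixture("B-P"),
            params=NMixParams(phi1=-0.7, phi2=-0.7),
            options=dict(K=50),
        ),
    }


PRESETS = (
    "well_identified_bp",
    "overdispersed_bbp",
    "ridge_j1",
    "glmm_nb",
    "tiny_toy",
    "bp_gof_calibration",
    "glmm_gof_calibration",
)


def make_fixture(preset: str, seed: int = 0) -> dict:
    """Full scenario bundle for a named preset.

    Returns a dict with keys ``sites``, ``checklists`` (with counts),
    ``truth``, ``spec``, ``params``, ``config`` and recommended fitting
    ``options``.
    """
    presets = _preset_specs()
    if preset not in presets:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(presets)}"
        )
    entry = presets[preset]
    config = replace(entry["config"], seed=seed)
    # visits drawn as 1 + Poisson(mean - 1); ridge_j1 forces exactly one
    sites, checklists = generate_design(config)
    if preset == "ridge_j1":
        checklists = checklists.groupby("site_id", sort=False).head(1).reset_index(drop=True)
    counts, truth = simulate_counts(
        (sites, checklists), entry["spec"], entry["params"], seed=seed + 1
    )
    return {
        "sites": sites,
        "checklists": counts,
        "truth": truth,
        "spec": entry["spec"],
        "params": entry["params"],
        "config": config,
        "options": dict(entry["options"]),
    }
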