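"""Canned study-condition scenarios with known ground truth.

These bundle the synthetic generators into the configurations the package's
validation rests on: an elk-like birth-pulse population on a 4 x 4 km
landscape, searching vs indifferent predators, and the end-to-end pipeline.
Scenario sizes are deliberately desk-scale (a few dozen animals over one
season) — small enough to replicate by the hundred, large enough for the
estimators to be in their asymptotic regime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import parturition, phenology, rsf, ssf
from .rasters import RasterStack
from .synth import (
    LandscapeConfig,
    PredatorBehaviorConfig,
    PreyBehaviorConfig,
    generate_landscape,
    simulate_predator,
    simulate_prey,
)

__all__ = [
    "default_landscape",
    "elk_prey_config",
    "cougar_config",
    "true_rsf_surface",
    "birth_pulse_weight",
    "ssf_replicate",
    "phenology_replicate",
    "run_pipeline",
]

BIRTH_PEAK_DOY = 147.0  # 27 May
BIRTH_SD_D = 7.0

# moderate landscape selection so the encounter effect must be separated
# from plain habitat preference
PREDATOR_BETA_TRUE = {"canopy": 0.3, "ruggedness": -0.2}
BIRTH_SITE_BETA = {"canopy": 0.5, "ruggedness": 0.3, "dist_road": 0.3}


def _sub(seed: int, k: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def default_landscape(seed: int = 0, extent: float = 4000.0) -> RasterStack:
    return generate_landscape(LandscapeConfig(extent=extent, seed=seed))


def elk_prey_config(**overrides) -> PreyBehaviorConfig:
    cfg = dict(
        species="elk",
        fix_interval_min=30.0,
        birth_doy_mean=BIRTH_PEAK_DOY,
        birth_doy_sd=BIRTH_SD_D,
        localization_radius_m=50.0,
        localization_duration_h=144.0,
        birth_site_beta=dict(BIRTH_SITE_BETA),
    )
    cfg.update(overrides)
    return PreyBehaviorConfig(**cfg)


def cougar_config(beta_enc: float = 0.0, **overrides) -> PredatorBehaviorConfig:
    cfg = dict(
        species="cougar",
        fix_interval_min=180.0,
        beta_true=dict(PREDATOR_BETA_TRUE),
        beta_enc=beta_enc,
    )
    cfg.update(overrides)
    return PredatorBehaviorConfig(**cfg)


def true_rsf_surface(landscape: RasterStack, beta: dict[str, float]) -> RasterStack:
    """Generative parturition-habitat surface exp(beta' z), z grid-standardized."""
    lin = np.zeros(landscape.shape)
    for name, b in beta.items():
        v = landscape.layers[name]
        lin = lin + b * (v - v.mean()) / v.std()
    return RasterStack(
        layers={"rsf_score": np.exp(lin)},
        cell_size=landscape.cell_size,
        origin=landscape.origin,
    )


def birth_pulse_weight(amplitude: float = 1.5, peak_doy: float = BIRTH_PEAK_DOY, sd_d: float = 12.0):
    """Gaussian day-of-year attraction weight centered on the birth pulse."""

    def weight(doy: float) -> float:
        return amplitude * np.exp(-0.5 * ((doy - peak_doy) / sd_d) ** 2)

    return weight


def ssf_replicate(
    beta_enc: float,
    seed: int,
    n_predators: int = 15,
    n_prey: int = 12,
    duration_d: float = 90.0,
    K: int = 20,
) -> ssf.SelectionFit:
    """One generative-recovery replicate: simulate, build strata, fit.

    Prey are elk with true (not detector-inferred) events, so the recovered
    encounter coefficient is compared against the generative truth without
    detector timing error.
    """
    land = default_landscape(_sub(seed, 0))
    prey_fixes, events = simulate_prey(
        elk_prey_config(), land, n_prey, _sub(seed, 1), duration_d=duration_d
    )
    pred_cfg = cougar_config(beta_enc=beta_enc)
    pred_fixes = simulate_predator(
        pred_cfg, land, prey_fixes, events, n_predators, _sub(seed, 2), duration_d=duration_d
    )
    design = ssf.build_strata(
        pred_fixes,
        land,
        prey_fixes=prey_fixes,
        events=events,
        K=K,
        seed=_sub(seed, 3),
        radius_m=pred_cfg.encounter_radius_m,
        postpartum_window_d=pred_cfg.postpartum_window_d,
        match_tolerance_min=pred_cfg.match_tolerance_min,
    )
    return ssf.fit_conditional_logistic(design)


def ssf_null_replicate(
    seed: int,
    n_predators: int = 6,
    n_prey: int = 10,
    duration_d: float = 45.0,
    K: int = 20,
) -> ssf.SelectionFit:
    """Size-check replicate: indifferent predators, full estimation model.

    Predators move with no selection at all (uniform among candidate steps),
    prey localize normally, and the analysis still estimates the encounter
    coefficient — the Wald test on it should reject at its nominal rate.
    Smaller than the recovery scenario so hundreds of replicates stay cheap.
    """
    land = default_landscape(_sub(seed, 0))
    prey_fixes, events = simulate_prey(
        elk_prey_config(), land, n_prey, _sub(seed, 1), duration_d=duration_d
    )
    pred_cfg = cougar_config(beta_enc=0.0, beta_true={})
    pred_fixes = simulate_predator(
        pred_cfg, land, prey_fixes, events, n_predators, _sub(seed, 2), duration_d=duration_d
    )
    design = ssf.build_strata(
        pred_fixes, land, prey_fixes=prey_fixes, events=events, K=K, seed=_sub(seed, 3)
    )
    return ssf.fit_conditional_logistic(design)


def phenology_replicate(
    searching: bool,
    seed: int,
    n_predators: int = 10,
    duration_d: float = 119.0,
    amplitude: float = 1.5,
) -> dict:
    """One phenology replicate: weekly use, both fits, LRT, peak week.

    ``searching=True`` gives predators a time-varying attraction to the
    parturition-habitat surface peaking at the birth pulse; ``False`` gives
    habitat-indifferent movement (the null).  The 15 analysis weeks span 15
    Apr-31 Jul; the simulation starts two weeks earlier as burn-in so
    animals have equilibrated within their home ranges before the window
    opens (the start-at-center transient otherwise mimics a seasonal trend).
    Weekly records require most of a week of fixes (>= 25 of ~56), dropping
    the truncated edge weeks.
    """
    land = default_landscape(_sub(seed, 0))
    surface = true_rsf_surface(land, BIRTH_SITE_BETA)
    # range-resident predators: weekly scores fluctuate about an animal-level
    # mean, which is what the random-intercept model describes
    cfg = cougar_config(beta_enc=0.0, home_range_strength=1.0)
    if searching:
        cfg.surface = surface.layers["rsf_score"]
        cfg.surface_weight = birth_pulse_weight(amplitude=amplitude)
    pred_fixes = simulate_predator(
        cfg, land, None, None, n_predators, _sub(seed, 1), start="2021-04-01", duration_d=duration_d
    )
    records = phenology.weekly_use(pred_fixes, surface, min_fixes=25)
    fit_q = phenology.fit_phenology(records, "quadratic")
    fit_l = phenology.fit_phenology(records, "linear")
    test = phenology.lrt(fit_q, fit_l)
    peak = None
    if fit_q.coef("week2") < 0:
        peak = phenology.peak_week(fit_q)
    return {
        "records": records,
        "linear": fit_l,
        "quadratic": fit_q,
        "lrt": test,
        "peak_week": peak,
    }


def run_pipeline(
    seed: int,
    n_prey: int = 12,
    n_predators: int = 10,
    beta_enc: float = 0.9,
    duration_d: float = 90.0,
) -> dict:
    """End-to-end chain on synthetic telemetry: detect births by rolling MCP,
    fit the SSF with the encounter covariate, fit the parturition RSF and
    project its surface, then test birth-pulse tracking of weekly use."""
    land = default_landscape(_sub(seed, 0))
    prey_fixes, truth = simulate_prey(
        elk_prey_config(), land, n_prey, _sub(seed, 1), duration_d=duration_d
    )
    detected = parturition.detect_all(prey_fixes, threshold_ha=30.0)
    detection_score = parturition.score_detections(detected, truth, max_offset_h=72.0)

    pred_cfg = cougar_config(beta_enc=beta_enc)
    pred_fixes = simulate_predator(
        pred_cfg, land, prey_fixes, truth, n_predators, _sub(seed, 2), duration_d=duration_d
    )
    design = ssf.build_strata(
        pred_fixes, land, prey_fixes=prey_fixes, events=detected, K=20, seed=_sub(seed, 3)
    )
    ssf_fit = ssf.fit_conditional_logistic(design)

    used = rsf.postpartum_used_points(prey_fixes, detected, days=7.0)
    polygon = rsf.elk_range_polygon(prey_fixes)
    available = rsf.draw_available(polygon, len(used), ratio=10.0, seed=_sub(seed, 4))
    rsf_fit = rsf.fit_rsf(used, available, land)
    surface = rsf.predict_surface(rsf_fit, land)

    records = phenology.weekly_use(pred_fixes, surface)
    fit_q = phenology.fit_phenology(records, "quadratic")
    fit_l = phenology.fit_phenology(records, "linear")
    test = phenology.lrt(fit_q, fit_l)

    return {
        "landscape": land,
        "prey_fixes": prey_fixes,
        "truth_events": truth,
        "detected_events": detected,
        "detection_score": detection_score,
        "predator_fixes": pred_fixes,
        "ssf_design": design,
        "ssf_fit": ssf_fit,
        "rsf_fit": rsf_fit,
        "surface": surface,
        "weekly_records": records,
        "phenology_linear": fit_l,
        "phenology_quadratic": fit_q,
        "phenology_lrt": test,
    }
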