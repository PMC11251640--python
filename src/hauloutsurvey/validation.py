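"""Truth-recovery experiments on synthetic surveys.

Because no field dataset ships with the package, the estimators are
validated by simulation: surveys are generated with known density,
dispersion and noise structure, the full pipeline is run on each, and the
estimates are compared with the known truth.  These experiments are what
the test suite and the acceptance script execute.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .counts import summarize_count_table, weighted_mean_density
from .estimators import direct_extrapolation, fit_linear, fit_nb_glm, predict_linear
from .geometry import DEFAULT_CELL_SIZE, DEFAULT_FRACTION, Terrain, select_model_polygons
from .synthetic import (
    DEFAULT_THETA,
    OutlineSpec,
    SimulationScenario,
    make_outline,
    simulate_cell_counts,
    simulate_survey,
)


def counting_reduction_experiment(
    n_surveys: int = 100,
    seed: int = 0,
    area_range: tuple = (5_000.0, 50_000.0),
    density: float = 0.76,
    theta: float = DEFAULT_THETA,
    cell_size: float = DEFAULT_CELL_SIZE,
    fraction: float = DEFAULT_FRACTION,
) -> dict:
    """How many animals never have to be counted when only the selected
    model polygons are counted instead of the whole haulout.

    Alternating rectangle and blob outlines with homogeneous density; for
    each survey the reduction is 100 x (1 - count in selected cells / total
    count).  Returns the mean and per-survey reductions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reductions = []
    for i in range(n_surveys):
        shape = "rectangle" if i % 2 == 0 else "blob"
        area = rng.uniform(*area_range)
        outline = make_outline(OutlineSpec(shape=shape, area=area),
                               seed=int(rng.integers(2**31)))
        cells, counts = simulate_cell_counts(outline, density, theta,
                                             cell_size=cell_size, rng=rng)
        select_model_polygons(cells, fraction=fraction, rng=rng)
        total = counts.sum()
        if total == 0:
            continue
        counted = sum(int(k) for c, k in zip(cells, counts) if c.selected)
        reductions.append(100.0 * (1.0 - counted / total))
    return {
        "mean_reduction_percent": float(np.mean(reductions)),
        "reductions": reductions,
        "n_surveys": len(reductions),
    }


def estimator_recovery_experiment(
    n_surveys: int = 200,
    seed: int = 0,
    area_range: tuple = (10_000.0, 30_000.0),
    cell_size: float = DEFAULT_CELL_SIZE,
    fraction: float = DEFAULT_FRACTION,
    n_sims: int = 2_000,
) -> dict:
    """Percent deviation of direct-extrapolation and linear-model estimates
    from the true (complete) count over many homogeneous synthetic surveys.

    Alternates rocky and sandy scenarios at their default densities with
    default observer noise.  Returns mean percent deviations per method.
    """
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master)
    dev_extrap, dev_linear = [], []
    for i in range(n_surveys):
        terrain = Terrain.ROCKY if i % 2 == 0 else Terrain.SANDY
        scenario = SimulationScenario(
            terrain=terrain,
            outline_spec=OutlineSpec(shape="blob" if i % 4 < 2 else "ellipse",
                                     area=float(rng.uniform(*area_range))),
            seed=int(rng.integers(2**31)),
        )
        survey = simulate_survey(scenario, cell_size=cell_size, fraction=fraction)
        truth = survey.complete_count
        if truth == 0:
            continue
        areas = {c.polygon_id: c.area for c in survey.cells}
        summaries = summarize_count_table(survey.observer_counts, areas)
        d_mean, d_sd = weighted_mean_density(summaries)
        est = direct_extrapolation(survey.outline.area, d_mean, d_sd,
                                   n_sims=n_sims, rng=rng)
        dev_extrap.append(100.0 * (est.point / truth - 1.0))
        if len(summaries) >= 3:
            plot_areas = [s.area for s in summaries]
            if np.ptp(plot_areas) > 0:
                import warnings

                fit = fit_linear([s.mean_count for s in summaries], plot_areas)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lin = predict_linear(fit, survey.outline.area)
                dev_linear.append(100.0 * (lin.point / truth - 1.0))
    return {
        "mean_deviation_extrapolation_percent": float(np.mean(dev_extrap)),
        "mean_deviation_linear_percent": float(np.mean(dev_linear)),
        "n_surveys": n_surveys,
    }


def nb_recovery_experiment(
    n_replicates: int = 100,
    n_polygons: int = 2_000,
    seed: int = 0,
    beta0: float = -0.434,
    beta_sandy: float = 0.305,
    theta: float = DEFAULT_THETA,
    polygon_area: float = DEFAULT_CELL_SIZE**2,
    z: float = 1.959964,
) -> dict:
    """Wald-CI coverage of the NB GLM refitted on data generated at known
    coefficients: half the plots rocky, half sandy, equal areas.

    Returns per-parameter counts of replicates whose 95% Wald interval
    covers the generating value.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    half = n_polygons // 2
    terr = np.array([Terrain.ROCKY.value] * half + [Terrain.SANDY.value] * half)
    areas = np.full(n_polygons, polygon_area)
    mu = np.exp(beta0 + beta_sandy * (terr == Terrain.SANDY.value)
                + np.log(areas))
    cover = {"intercept": 0, "sandy_coef": 0, "theta": 0}
    estimates = []
    for _ in range(n_replicates):
        y = rng.negative_binomial(theta, theta / (theta + mu))
        fit = fit_nb_glm(y, areas, terr)
        se = fit.se_params
        if abs(fit.intercept - beta0) <= z * se[0]:
            cover["intercept"] += 1
        if abs(fit.sandy_coef - beta_sandy) <= z * se[1]:
            cover["sandy_coef"] += 1
        if fit.se_theta and abs(fit.theta - theta) <= z * fit.se_theta:
            cover["theta"] += 1
        estimates.append((fit.intercept, fit.sandy_coef, fit.theta))
    est = np.array(estimates)
    return {
        "coverage": cover,
        "n_replicates": n_replicates,
        "mean_estimates": {"intercept": float(est[:, 0].mean()),
                           "sandy_coef": float(est[:, 1].mean()),
                           "theta": float(est[:, 2].mean())},
    }
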