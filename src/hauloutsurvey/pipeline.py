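"""End-to-end pipeline driver: grid -> sample -> summarize -> estimate -> compare.

Two modes:

* ``simulate`` — self-contained: generates one survey per configured
  scenario, runs every estimator, and compares against the known complete
  counts (the recommended way to validate the estimators);
* ``files`` — reads outlines (GeoJSON) and per-plot observer counts (CSV)
  and produces summaries and estimates for real survey data.

Every run writes a manifest (config hash, seed, package and library
versions) next to its outputs, and a fixed seed makes outputs byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import compare_to_complete
from .counts import agreement_report, summarize_count_table, weighted_mean_density
from .estimators import (
    AbundanceEstimate,
    NBModelFit,
    direct_extrapolation,
    fit_linear,
    fit_nb_glm,
    predict_linear,
    predict_nb,
)
from .geometry import DEFAULT_CELL_SIZE, DEFAULT_FRACTION, generate_grid, select_model_polygons
from .io import (
    read_counts,
    read_outlines,
    write_cells,
    write_comparisons,
    write_counts,
    write_estimates,
    write_json,
    write_model_fit,
    write_outlines,
    write_summaries,
)
from .synthetic import SimulationScenario, simulate_survey

log = logging.getLogger("hauloutsurvey")

_METHODS = ("extrapolation", "linear", "nbglm")


@dataclass
class PipelineConfig:
    mode: str = "simulate"                     # "simulate" | "files"
    cell_size: float = DEFAULT_CELL_SIZE       # m
    fraction: float = DEFAULT_FRACTION         # plot selection fraction
    n_sims: int = 10_000                       # normal draws for the simulation CI
    z: float = 1.96                            # critical value for the linear CI
    seed: int = 0
    methods: tuple = _METHODS
    crs_label: str = "EPSG:32602"
    weighted_sd: bool = True                   # area-weighted density SD in the CI
    scenarios: list = field(default_factory=list)   # simulate mode
    outlines_path: "str | None" = None              # files mode
    counts_path: "str | None" = None                # files mode
    outdir: str = "hauloutsurvey-output"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.n_sims < 100:
            raise ValueError("n_sims must be at least 100")
        if self.z <= 0:
            raise ValueError("z must be positive")
        bad = [m for m in self.methods if m not in _METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; allowed: {_METHODS}")
        self.methods = tuple(self.methods)
        self.scenarios = [
            s if isinstance(s, SimulationScenario) else SimulationScenario(**s)
            for s in self.scenarios
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["scenarios"] = [s.to_dict() for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class PipelineResult:
    estimates: list
    comparisons: list
    comparison_summary: dict
    agreement: dict
    nb_fit: "NBModelFit | None"
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full pipeline and write all artifacts to the output dir."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if config.mode == "simulate":
            result = _run_simulate(config, outdir)
        else:
            result = _run_files(config, outdir)
    except Exception as e:
        raise RuntimeError(f"pipeline failed in {config.mode!r} mode: {e}") from e
    manifest = _manifest(config)
    write_json(manifest, outdir / "manifest.json")
    result.manifest = manifest
    return result


def _manifest(config: PipelineConfig) -> dict:
    import scipy
    import shapely
    import statsmodels

    return {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {
            "hauloutsurvey": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "shapely": shapely.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def _survey_estimates(config, site_id, survey_date, summaries, haulout_area, rng):
    """Per-survey extrapolation and linear-model estimates."""
    ests = []
    d_mean, d_sd = weighted_mean_density(summaries, weighted=config.weighted_sd)
    if "extrapolation" in config.methods:
        ests.append(direct_extrapolation(
            haulout_area, d_mean, d_sd, n_sims=config.n_sims, rng=rng,
            site_id=site_id, survey_date=survey_date, n_polygons=len(summaries),
        ))
    if "linear" in config.methods and len(summaries) >= 3:
        counts = [s.mean_count for s in summaries]
        areas = [s.area for s in summaries]
        if np.ptp(areas) > 0:
            import warnings as _w

            fit = fit_linear(counts, areas)
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # whole-haulout extrapolation is intended
                ests.append(predict_linear(fit, haulout_area, z=config.z,
                                           site_id=site_id, survey_date=survey_date))
    return ests


def _run_simulate(config: PipelineConfig, outdir: Path) -> PipelineResult:
    if not config.scenarios:
        raise ValueError("simulate mode needs at least one scenario")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    estimates, complete, all_summaries = [], {}, []
    pooled_counts, pooled_areas, pooled_terrain = [], [], []
    outlines, all_cells, count_frames = [], [], []
    per_survey = []

    for i, base in enumerate(config.scenarios):
        site_id = base.site_id if base.site_id != "synthetic-site" else f"site-{i}"
        scenario = dataclasses.replace(base, seed=base.seed + config.seed,
                                       site_id=site_id)
        survey = simulate_survey(scenario, cell_size=config.cell_size,
                                 fraction=config.fraction)
        outlines.append(survey.outline)
        all_cells.extend(survey.cells)
        count_frames.append(survey.observer_counts)
        areas = {c.polygon_id: c.area for c in survey.cells}
        summaries = summarize_count_table(survey.observer_counts, areas)
        all_summaries.extend(summaries)
        key = (scenario.site_id, scenario.survey_date)
        complete[key] = survey.complete_count
        log.info("survey %s: area %.0f m^2, %d cells, %d selected, complete count %d",
                 key, survey.outline.area, len(survey.cells),
                 sum(c.selected for c in survey.cells), survey.complete_count)
        estimates.extend(_survey_estimates(
            config, scenario.site_id, scenario.survey_date, summaries,
            survey.outline.area, rng))
        estimates.append(AbundanceEstimate(
            method="land_visual", site_id=scenario.site_id,
            survey_date=scenario.survey_date, point=float(survey.land_count),
            ci_lower=float(survey.land_count), ci_upper=float(survey.land_count)))
        per_survey.append((scenario, survey, summaries))
        pooled_counts += [s.mean_count for s in summaries]
        pooled_areas += [s.area for s in summaries]
        pooled_terrain += [scenario.terrain] * len(summaries)

    nb_fit = None
    if "nbglm" in config.methods and len(pooled_counts) >= 4:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)  # single-level pools are fine
            nb_fit = fit_nb_glm(pooled_counts, pooled_areas, pooled_terrain)
        for scenario, survey, _ in per_survey:
            estimates.append(predict_nb(nb_fit, survey.outline.area,
                                        scenario.terrain, site_id=scenario.site_id,
                                        survey_date=scenario.survey_date))
        write_model_fit(nb_fit, outdir / "nb_glm_fit.json")

    records, summary, _ = compare_to_complete(estimates, complete)
    agreement = agreement_report(all_summaries)

    write_outlines(outlines, outdir / "outlines.geojson")
    write_cells(all_cells, outdir / "cells.geojson", crs_label=config.crs_label)
    write_counts(pd.concat(count_frames, ignore_index=True), outdir / "counts.csv")
    write_summaries(all_summaries, outdir / "summaries.csv")
    write_estimates(estimates, outdir / "estimates.csv")
    write_comparisons(records, outdir / "comparisons.csv")
    write_json({"comparison_summary": summary, "observer_agreement": agreement},
               outdir / "comparison_summary.json")
    return PipelineResult(estimates, records, summary, agreement, nb_fit, {})


def _run_files(config: PipelineConfig, outdir: Path) -> PipelineResult:
    if not config.outlines_path or not config.counts_path:
        raise ValueError("files mode needs outlines_path and counts_path")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    outlines = read_outlines(config.outlines_path)

    all_cells = []
    for outline in outlines:
        cells = generate_grid(outline, cell_size=config.cell_size)
        select_model_polygons(cells, fraction=config.fraction, rng=rng)
        all_cells.extend(cells)
    counts = read_counts(config.counts_path,
                         known_ids={c.polygon_id for c in all_cells})
    areas = {c.polygon_id: c.area for c in all_cells}

    estimates, all_summaries = [], []
    for outline in outlines:
        ids = {c.polygon_id for c in all_cells if c.site_id == outline.site_id
               and c.survey_date == outline.survey_date}
        sub = counts[counts["polygon_id"].isin(ids)]
        if sub.empty:
            continue
        summaries = summarize_count_table(sub, areas)
        all_summaries.extend(summaries)
        estimates.extend(_survey_estimates(
            config, outline.site_id, outline.survey_date, summaries,
            outline.area, rng))

    write_cells(all_cells, outdir / "cells.geojson", crs_label=config.crs_label)
    write_summaries(all_summaries, outdir / "summaries.csv")
    write_estimates(estimates, outdir / "estimates.csv")
    agreement = agreement_report(all_summaries)
    write_json({"observer_agreement": agreement}, outdir / "comparison_summary.json")
    return PipelineResult(estimates, [], {}, agreement, None, {})
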