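"""Per-plot count summaries, densities, and observer agreement.

Each model polygon may be counted by several observers.  Counts are reduced
to a mean, a sample SD (n - 1 denominator) and a CV (%); the plot density is
the mean count divided by plot area.  The survey-level density is the
area-weighted mean of plot densities, which algebraically equals the ratio
estimator total-count / total-area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PolygonCountSummary:
    """Observer counts of one model polygon reduced to summary statistics.

    ``sd_count`` and ``cv`` are None when only one observer counted the plot
    (neither can be estimated) and ``cv`` is also None when the mean is zero.
    """

    polygon_id: str
    n_observers: int
    mean_count: float
    sd_count: "float | None"
    cv: "float | None"           # percent
    area: "float | None" = None  # m^2
    density: "float | None" = None  # walrus per m^2
    qc_excluded: bool = False


def summarize_counts(counts, polygon_id: str = "") -> PolygonCountSummary:
    """Mean, sample SD and CV (%) of one plot's per-observer counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one observer count")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    mean = float(arr.mean())
    if arr.size == 1:
        sd = cv = None
    else:
        sd = float(arr.std(ddof=1))
        cv = 100.0 * sd / mean if mean > 0 else None
    return PolygonCountSummary(
        polygon_id=polygon_id, n_observers=int(arr.size),
        mean_count=mean, sd_count=sd, cv=cv,
    )


def polygon_density(summary: PolygonCountSummary, area: float) -> float:
    """Attach the plot area and return density = mean count / area (per m^2)."""
    if area <= 0:
        raise ValueError(f"polygon {summary.polygon_id!r}: area must be positive")
    summary.area = float(area)
    summary.density = summary.mean_count / area
    return summary.density


def summarize_count_table(
    counts: pd.DataFrame,
    areas: "dict[str, float]",
    qc_excluded: "set[str] | None" = None,
) -> list[PolygonCountSummary]:
    """Reduce a tidy (polygon_id, observer_id, count) table to per-plot
    summaries with densities; QC-excluded plots are dropped entirely."""
    qc_excluded = qc_excluded or set()
    out = []
    for pid, grp in counts.groupby("polygon_id", sort=True):
        if pid in qc_excluded:
            continue
        s = summarize_counts(grp["count"].to_numpy(), polygon_id=str(pid))
        if pid not in areas:
            raise KeyError(f"no area known for polygon_id {pid!r}")
        polygon_density(s, areas[pid])
        out.append(s)
    return out


def weighted_mean_density(
    summaries: "list[PolygonCountSummary]", weighted: bool = True
) -> tuple[float, float]:
    """Survey-level density: area-weighted mean of plot densities and its SD.

    The weighted mean Sum(a_i d_i)/Sum(a_i) equals the ratio estimator
    Sum(mean counts)/Sum(areas) exactly.  The SD is the area-weighted SD of
    plot densities about that mean (frequency-style weights a_i/Sum(a_i));
    with ``weighted=False`` both statistics are unweighted (sample SD,
    n - 1 denominator), for sensitivity checks.
    """
    use = [s for s in summaries if not s.qc_excluded and s.density is not None]
    if not use:
        raise ValueError("no usable polygon summaries (all excluded or without density)")
    d = np.array([s.density for s in use])
    a = np.array([s.area for s in use])
    if weighted:
        w = a / a.sum()
        mean = float(w @ d)
        sd = float(math.sqrt(w @ (d - mean) ** 2))
    else:
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return mean, sd


def agreement_report(summaries: "list[PolygonCountSummary]") -> dict:
    """Descriptive statistics of observer agreement (CV %) across plots
    counted by at least two observers."""
    multi = [s for s in summaries if s.n_observers >= 2 and s.cv is not None]
    single = sum(1 for s in summaries if s.n_observers == 1)
    cvs = np.array([s.cv for s in multi])
    report = {
        "n_multi_observer": len(multi),
        "n_single_observer": single,
        "min_cv": float(cvs.min()) if cvs.size else None,
        "mean_cv": float(cvs.mean()) if cvs.size else None,
        "sd_cv": float(cvs.std(ddof=1)) if cvs.size > 1 else None,
        "max_cv": float(cvs.max()) if cvs.size else None,
    }
    return report
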