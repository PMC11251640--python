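"""Readers and writers for survey artifacts.

Outlines, model polygons and point sets travel as GeoJSON FeatureCollections
with *planar meter* coordinates; the projected CRS is recorded as a
file-level ``crs_label`` property rather than re-projected (GeoJSON's
default CRS is geographic — the deviation is deliberate and documented in
the repository docs).  Counts, summaries, estimates and comparisons are
plain CSV with fixed float formatting and stable row order, so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .comparison import ComparisonRecord
from .counts import PolygonCountSummary
from .estimators import AbundanceEstimate, NBModelFit
from .geometry import GeometryError, HauloutOutline, ModelPolygon, Terrain
from .synthetic import WalrusPointSet

FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    """Input file fails validation against the expected schema."""


def _check_polygon(geom, what: str) -> Polygon:
    if not isinstance(geom, Polygon):
        raise SchemaError(f"{what}: geometry must be a Polygon, got {geom.geom_type}")
    if not geom.is_valid:
        import shapely.validation

        raise SchemaError(f"{what}: {shapely.validation.explain_validity(geom)}")
    return geom


# ------------------------------------------------------------------- outlines


def write_outlines(outlines: "list[HauloutOutline]", path) -> None:
    feats = []
    for o in outlines:
        feats.append({
            "type": "Feature",
            "geometry": mapping(o.polygon),
            "properties": {
                "site_id": o.site_id,
                "survey_date": o.survey_date.isoformat(),
                "terrain": o.terrain.value,
                "area_m2": round(o.area, 6),
            },
        })
    fc = {"type": "FeatureCollection",
          "crs_label": outlines[0].crs_label if outlines else "unknown",
          "features": feats}
    Path(path).write_text(json.dumps(fc, indent=1, sort_keys=True) + "\n")


def read_outlines(path) -> "list[HauloutOutline]":
    fc = json.loads(Path(path).read_text())
    crs = fc.get("crs_label", "unknown")
    out = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        what = f"outline feature {i} ({props.get('site_id', '?')})"
        for req in ("site_id", "survey_date", "terrain"):
            if req not in props:
                raise SchemaError(f"{what}: missing property {req!r}")
        geom = _check_polygon(shape(feat["geometry"]), what)
        try:
            terrain = Terrain.from_label(props["terrain"])
        except ValueError as e:
            raise SchemaError(f"{what}: {e}") from None
        try:
            out.append(HauloutOutline(
                site_id=str(props["site_id"]),
                survey_date=dt.date.fromisoformat(props["survey_date"]),
                terrain=terrain, polygon=geom, crs_label=crs,
            ))
        except GeometryError as e:
            raise SchemaError(f"{what}: {e}") from None
    return out


# -------------------------------------------------------------- model polygons


def write_cells(cells: "list[ModelPolygon]", path, crs_label: str = "EPSG:32602") -> None:
    feats = [{
        "type": "Feature",
        "geometry": mapping(c.geometry),
        "properties": {
            "polygon_id": c.polygon_id,
            "site_id": c.site_id,
            "survey_date": c.survey_date.isoformat(),
            "area_m2": round(c.area, 6),
            "selected": bool(c.selected),
            "qc_excluded": bool(c.qc_excluded),
        },
    } for c in cells]
    fc = {"type": "FeatureCollection", "crs_label": crs_label, "features": feats}
    Path(path).write_text(json.dumps(fc, indent=1, sort_keys=True) + "\n")


def read_cells(path) -> "list[ModelPolygon]":
    fc = json.loads(Path(path).read_text())
    out = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        what = f"cell feature {i} ({props.get('polygon_id', '?')})"
        if "polygon_id" not in props:
            raise SchemaError(f"{what}: missing property 'polygon_id'")
        out.append(ModelPolygon(
            polygon_id=str(props["polygon_id"]),
            site_id=str(props.get("site_id", "")),
            survey_date=dt.date.fromisoformat(props["survey_date"]),
            geometry=_check_polygon(shape(feat["geometry"]), what),
            selected=bool(props.get("selected", False)),
            qc_excluded=bool(props.get("qc_excluded", False)),
        ))
    return out


def write_points(points: WalrusPointSet, path, crs_label: str = "EPSG:32602") -> None:
    fc = {
        "type": "FeatureCollection",
        "crs_label": crs_label,
        "features": [{
            "type": "Feature",
            "geometry": {"type": "MultiPoint",
                         "coordinates": np.round(points.points, 6).tolist()},
            "properties": {"site_id": points.outline.site_id,
                           "survey_date": points.outline.survey_date.isoformat(),
                           "complete_count": points.complete_count},
        }],
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True) + "\n")


# ----------------------------------------------------------------------- CSVs

COUNT_COLUMNS = ["polygon_id", "observer_id", "count"]


def read_counts(path, known_ids=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"counts file {path}: missing columns {missing}")
    if df["count"].isna().any() or (df["count"] < 0).any():
        raise SchemaError(f"counts file {path}: counts must be non-negative integers")
    if known_ids is not None:
        unknown = sorted(set(df["polygon_id"].astype(str)) - set(known_ids))
        if unknown:
            raise SchemaError(
                f"counts file {path}: polygon_id(s) not present in the "
                f"geometry inputs: {', '.join(unknown[:10])}"
            )
    return df[COUNT_COLUMNS].copy()


def write_counts(df: pd.DataFrame, path) -> None:
    df = df[COUNT_COLUMNS].sort_values(COUNT_COLUMNS[:2], kind="stable")
    df.to_csv(path, index=False)


def write_summaries(summaries: "list[PolygonCountSummary]", path) -> None:
    rows = [{
        "polygon_id": s.polygon_id, "n_observers": s.n_observers,
        "mean_count": s.mean_count, "sd_count": s.sd_count, "cv_percent": s.cv,
        "area_m2": s.area, "density_per_m2": s.density,
    } for s in sorted(summaries, key=lambda s: s.polygon_id)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


ESTIMATE_COLUMNS = ["site_id", "survey_date", "method", "point",
                    "ci_lower", "ci_upper", "n_polygons"]


def write_estimates(estimates: "list[AbundanceEstimate]", path) -> None:
    rows = [{
        "site_id": e.site_id,
        "survey_date": e.survey_date.isoformat() if e.survey_date else "",
        "method": e.method, "point": e.point,
        "ci_lower": e.ci_lower, "ci_upper": e.ci_upper,
        "n_polygons": e.n_polygons,
    } for e in estimates]
    df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    df = df.sort_values(["site_id", "survey_date", "method"], kind="stable")
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_estimates(path) -> "list[AbundanceEstimate]":
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"estimates file {path}: missing columns {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(AbundanceEstimate(
            method=str(r["method"]), site_id=str(r["site_id"]),
            survey_date=dt.date.fromisoformat(str(r["survey_date"]))
            if r["survey_date"] else None,
            point=float(r["point"]), ci_lower=float(r["ci_lower"]),
            ci_upper=float(r["ci_upper"]),
            n_polygons=None if pd.isna(r["n_polygons"]) else int(r["n_polygons"]),
        ))
    return out


def write_comparisons(records: "list[ComparisonRecord]", path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    for r in rows:
        if isinstance(r["survey_date"], dt.date):
            r["survey_date"] = r["survey_date"].isoformat()
    df = pd.DataFrame(rows, columns=["site_id", "survey_date", "method",
                                     "predicted", "complete", "ratio",
                                     "percent_deviation"])
    df = df.sort_values(["site_id", "survey_date", "method"], kind="stable")
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ----------------------------------------------------------------- model dumps


def write_model_fit(fit: NBModelFit, path) -> None:
    d = {
        "params": fit.params.tolist(),
        "cov": fit.cov.tolist(),
        "terrain_levels": list(fit.terrain_levels),
        "theta": fit.theta, "se_theta": fit.se_theta,
        "null_deviance": fit.null_deviance,
        "resid_deviance": fit.resid_deviance,
        "deviance_explained_percent":
            fit.deviance_explained if fit.null_deviance > 0 else None,
        "loglik": fit.loglik, "n_obs": fit.n_obs,
        "converged": fit.converged, "n_iter": fit.n_iter,
    }
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


def read_model_fit(path) -> NBModelFit:
    d = json.loads(Path(path).read_text())
    return NBModelFit(
        params=np.array(d["params"]), cov=np.array(d["cov"]),
        terrain_levels=tuple(d["terrain_levels"]), theta=d["theta"],
        se_theta=d["se_theta"], null_deviance=d["null_deviance"],
        resid_deviance=d["resid_deviance"], loglik=d["loglik"],
        n_obs=d["n_obs"], converged=d["converged"], n_iter=d["n_iter"],
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
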