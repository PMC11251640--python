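"""Planar geometry for haulout survey sampling.

Haulout outlines are simple polygons in projected meter coordinates (the
surveys this package emulates used a UTM projection; no geodesy is performed
here — reprojecting to a planar CRS is the caller's responsibility).  A
square grid is laid over each outline, clipped to it, and a fixed fraction of
the clipped cells is drawn uniformly at random as "model polygons": the plots
inside which animals are exhaustively counted.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

#: Default grid cell edge in meters.
DEFAULT_CELL_SIZE = 19.68

#: Default fraction of clipped cells selected as model polygons.
DEFAULT_FRACTION = 0.30

#: Clipped fragments smaller than this (m^2) are discarded as slivers to
#: avoid degenerate densities from near-zero plot areas.
SLIVER_AREA = 0.01


class Terrain(str, enum.Enum):
    """Binary haulout terrain classification.

    ``rocky_type`` — rocky shore with boulders/cliffs, spatially restricted;
    ``sandy_type`` — flat sandy beach, spatially unrestricted.
    """

    ROCKY = "rocky_type"
    SANDY = "sandy_type"

    @classmethod
    def from_label(cls, label: "str | Terrain") -> "Terrain":
        if isinstance(label, Terrain):
            return label
        try:
            return cls(label)
        except ValueError:
            allowed = ", ".join(t.value for t in cls)
            raise ValueError(
                f"unknown terrain {label!r}; allowed terrain labels: {allowed}"
            ) from None


class GeometryError(ValueError):
    """Invalid ring, polygon, or grid input."""


def _close_ring(ring: np.ndarray) -> np.ndarray:
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise GeometryError("a ring must be an (n, 2) array of planar coordinates")
    n_distinct = len(np.unique(ring, axis=0))
    if n_distinct < 3:
        raise GeometryError(f"a ring needs at least 3 distinct vertices, got {n_distinct}")
    if not np.allclose(ring[0], ring[-1]):
        raise GeometryError(
            "open ring: first and last vertex differ "
            f"({tuple(ring[0])} vs {tuple(ring[-1])})"
        )
    return ring


def rings_to_polygon(rings) -> Polygon:
    """Build a shapely polygon from [exterior, *holes] coordinate rings.

    Every ring must be explicitly closed (first vertex == last vertex).
    """
    if not rings:
        raise GeometryError("no rings given")
    closed = [_close_ring(r) for r in rings]
    poly = Polygon(closed[0], holes=closed[1:] or None)
    if not poly.is_valid:
        raise GeometryError(f"invalid polygon: {shapely.validation.explain_validity(poly)}")
    return poly


def polygon_area(rings) -> float:
    """Shoelace area (m^2) of an exterior ring minus any hole rings.

    Invariant to vertex orientation and to translation of all rings.
    """
    return rings_to_polygon(rings).area


@dataclass
class HauloutOutline:
    """A dated, terrain-typed polygon delimiting the herd's footprint on shore."""

    site_id: str
    survey_date: dt.date
    terrain: Terrain
    polygon: Polygon
    crs_label: str = "EPSG:32602"

    def __post_init__(self) -> None:
        self.terrain = Terrain.from_label(self.terrain)
        if not isinstance(self.polygon, Polygon) or self.polygon.is_empty:
            raise GeometryError(f"outline {self.site_id!r}: geometry must be a non-empty polygon")
        if not self.polygon.is_valid:
            raise GeometryError(
                f"outline {self.site_id!r}: "
                f"{shapely.validation.explain_validity(self.polygon)}"
            )
        if self.polygon.area <= 0:
            raise GeometryError(f"outline {self.site_id!r}: area must be positive")

    @property
    def area(self) -> float:
        """Outline area in m^2."""
        return self.polygon.area

    @property
    def key(self) -> tuple[str, dt.date]:
        return (self.site_id, self.survey_date)


@dataclass
class ModelPolygon:
    """A clipped grid cell (or arbitrary section) used as a counting plot."""

    polygon_id: str
    site_id: str
    survey_date: dt.date
    geometry: Polygon
    selected: bool = False
    qc_excluded: bool = False

    @property
    def area(self) -> float:
        """Plot area a_i in m^2."""
        return self.geometry.area


def generate_grid(
    outline: HauloutOutline,
    cell_size: float = DEFAULT_CELL_SIZE,
    origin: "tuple[float, float] | None" = None,
    min_fragment_area: float = SLIVER_AREA,
) -> list[ModelPolygon]:
    """Lay a square grid over the outline's bounding box and clip every cell.

    Cells are axis-aligned squares of side ``cell_size`` anchored at ``origin``
    (default: the bounding-box minimum corner).  Each cell is intersected with
    the outline; empty intersections are dropped, and a cell whose clipped
    geometry splits into several parts yields one model polygon per part with
    a ``_p<k>`` id suffix.  Fragments below ``min_fragment_area`` are
    discarded (pass 0 to keep everything; with 0 the clipped areas sum exactly
    to the outline area).
    """
    if cell_size <= 0:
        raise GeometryError("cell_size must be positive")
    poly = outline.polygon
    if poly.area <= 0:
        raise GeometryError("degenerate outline with zero area")
    minx, miny, maxx, maxy = poly.bounds
    ox, oy = origin if origin is not None else (minx, miny)
    # shift the anchor down-left so the grid still covers the bbox
    ox -= math.ceil(max(0.0, (ox - minx)) / cell_size) * cell_size
    oy -= math.ceil(max(0.0, (oy - miny)) / cell_size) * cell_size
    nx = max(1, math.ceil((maxx - ox) / cell_size - 1e-12))
    ny = max(1, math.ceil((maxy - oy) / cell_size - 1e-12))

    cells: list[ModelPolygon] = []
    for j in range(ny):
        for i in range(nx):
            cell = box(ox + i * cell_size, oy + j * cell_size,
                       ox + (i + 1) * cell_size, oy + (j + 1) * cell_size)
            clipped = cell.intersection(poly)
            if clipped.is_empty:
                continue
            parts = _polygon_parts(clipped)
            multi = len(parts) > 1
            for k, part in enumerate(parts):
                if part.area < min_fragment_area:
                    continue
                pid = f"{outline.site_id}-{outline.survey_date.isoformat()}-r{j:03d}c{i:03d}"
                if multi:
                    pid += f"_p{k}"
                cells.append(
                    ModelPolygon(
                        polygon_id=pid,
                        site_id=outline.site_id,
                        survey_date=outline.survey_date,
                        geometry=part,
                    )
                )
    return cells


def _polygon_parts(geom: BaseGeometry) -> list[Polygon]:
    """Polygonal components of an intersection result (lines/points dropped)."""
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon) and g.area > 0]


def random_grid_origin(
    outline: HauloutOutline, cell_size: float, rng: np.random.Generator
) -> tuple[float, float]:
    """A uniformly jittered grid anchor, for grid-placement sensitivity checks."""
    minx, miny = outline.polygon.bounds[:2]
    dx, dy = rng.uniform(-cell_size, 0.0, size=2)
    return (minx + dx, miny + dy)


def sample_size(n_cells: int, fraction: float) -> int:
    """Round-half-up of fraction x n, floored at one plot."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, int(math.floor(fraction * n_cells + 0.5)))


def select_model_polygons(
    cells: list[ModelPolygon],
    fraction: float = DEFAULT_FRACTION,
    seed: "int | None" = None,
    rng: "np.random.Generator | None" = None,
) -> list[ModelPolygon]:
    """Mark a uniform random sample of cells as selected model polygons.

    Selects ``round(fraction * n)`` cells (minimum 1) without replacement and
    sets their ``selected`` flags in place; deterministic for a fixed seed.
    Returns the same list.
    """
    if not cells:
        raise ValueError("cannot sample from an empty cell list")
    rng = rng if rng is not None else np.random.default_rng(seed)
    k = sample_size(len(cells), fraction)
    chosen = rng.choice(len(cells), size=k, replace=False)
    for c in cells:
        c.selected = False
    for i in chosen:
        cells[int(i)].selected = True
    return cells
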