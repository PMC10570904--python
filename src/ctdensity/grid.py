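"""Hexagonal site grid for discretizing a study area.

Site-structured abundance models need counts at discrete sites, so the
study area is tessellated with equal-area hexagons and each camera is
assigned to the cell containing it.  Hexagons are flat-top, anchored at
the lower-left corner of the bounding box; every cell intersecting the
box is retained, so the grid *covers* the box (total cell area exceeds
the box area by a boundary ring).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box

__all__ = ["HexGrid", "build_hex_grid", "build_hex_grid_for_polygon",
           "load_study_area", "assign_sites"]

_SQRT3 = math.sqrt(3.0)


@dataclass
class HexGrid:
    """Equal-area flat-top hexagon tessellation covering a bounding box."""

    polygons: list[Polygon]
    centroids: np.ndarray  # (n_cells, 2) km
    cell_area_km2: float
    bbox: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    @property
    def n_cells(self) -> int:
        return len(self.polygons)

    def metadata(self) -> dict:
        """JSON-serializable description (for the count-table sidecar)."""
        return {
            "n_cells": self.n_cells,
            "cell_area_km2": self.cell_area_km2,
            "bbox": list(self.bbox),
            "orientation": "flat-top",
            "centroids": self.centroids.tolist(),
        }


def _hexagon(cx: float, cy: float, circumradius: float) -> Polygon:
    ang = np.arange(6) * (math.pi / 3.0)
    return Polygon(
        np.column_stack(
            [cx + circumradius * np.cos(ang), cy + circumradius * np.sin(ang)]
        )
    )


def build_hex_grid(
    bbox: tuple[float, float, float, float], cell_area_km2: float
) -> HexGrid:
    """Tessellate ``bbox`` (xmin, ymin, xmax, ymax, in km) with hexagons.

    Every hexagon whose interior intersects the box is kept; cell ids run
    column-major from the lower-left anchor.  A cell area exceeding the
    box area yields a single-cell (or near-single) grid with a warning.
    """
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bbox is degenerate")
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    box_area = (xmax - xmin) * (ymax - ymin)
    if cell_area_km2 > box_area:
        warnings.warn(
            "cell area exceeds bounding-box area; grid degenerates to a "
            "single ring of cells",
            stacklevel=2,
        )

    # area = (3*sqrt(3)/2) * R^2 for circumradius R
    R = math.sqrt(2.0 * cell_area_km2 / (3.0 * _SQRT3))
    dx = 1.5 * R          # column pitch
    dy = _SQRT3 * R       # row pitch

    n_cols = int(math.ceil((xmax - xmin) / dx)) + 2
    n_rows = int(math.ceil((ymax - ymin) / dy)) + 2
    bbox_poly = box(xmin, ymin, xmax, ymax)

    polygons: list[Polygon] = []
    centroids: list[tuple[float, float]] = []
    for q in range(-1, n_cols):
        cx = xmin + q * dx
        y_off = (dy / 2.0) if (q % 2) else 0.0
        for k in range(-1, n_rows):
            cy = ymin + k * dy + y_off
            hexagon = _hexagon(cx, cy, R)
            inter = hexagon.intersection(bbox_poly)
            if inter.area > 1e-9 * cell_area_km2:
                polygons.append(hexagon)
                centroids.append((cx, cy))

    return HexGrid(
        polygons=polygons,
        centroids=np.asarray(centroids, dtype=float),
        cell_area_km2=cell_area_km2,
        bbox=(xmin, ymin, xmax, ymax),
    )


def load_study_area(path) -> Polygon:
    """Read a study-area polygon from a GeoJSON file (planar km coords)."""
    import json

    from shapely.geometry import shape

    data = json.loads(open(path).read())
    if data.get("type") == "FeatureCollection":
        geom = shape(data["features"][0]["geometry"])
    elif data.get("type") == "Feature":
        geom = shape(data["geometry"])
    else:
        geom = shape(data)
    return geom


def build_hex_grid_for_polygon(polygon: Polygon, cell_area_km2: float) -> HexGrid:
    """Tessellate a study-area polygon, keeping cells that intersect it."""
    grid = build_hex_grid(polygon.bounds, cell_area_km2)
    keep = [
        k for k, poly in enumerate(grid.polygons)
        if poly.intersection(polygon).area > 1e-9 * cell_area_km2
    ]
    return HexGrid(
        polygons=[grid.polygons[k] for k in keep],
        centroids=grid.centroids[keep],
        cell_area_km2=cell_area_km2,
        bbox=polygon.bounds,
    )


def assign_sites(deployments: Sequence, grid: HexGrid) -> Mapping[str, int]:
    """Map each camera to the grid cell containing it.

    Boundary ties (a camera exactly on a shared edge) break to the lowest
    cell id.  A camera outside every cell raises ``KeyError`` naming it.
    """
    mapping: dict[str, int] = {}
    for dep in deployments:
        pt = Point(dep.x_km, dep.y_km)
        cell = next(
            (i for i, poly in enumerate(grid.polygons) if poly.covers(pt)), None
        )
        if cell is None:
            raise KeyError(
                f"camera {dep.camera_id!r} at ({dep.x_km}, {dep.y_km}) lies "
                "outside the grid"
            )
        mapping[dep.camera_id] = cell
    return mapping
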