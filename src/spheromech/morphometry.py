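"""TEM cross-section morphometry.

Implements the image-analysis protocol applied to stitched TEM strips of
spheroid middle sections: per-cell and per-nucleus areas from traced
outlines, exclusion of incomplete cells (those not showing the entire
outline and whole nucleus inside a panel), partition of the primary-axis
extent into the inner 50% and the two outer 25% flanks, selection of the
center / outermost-edge-free panels, and the intercellular-space density
(uncovered fraction of a panel after filling the traced cell outlines).

Coordinates are strip-frame μm: x along the primary axis with origin at
the left spheroid edge, y across the strip.  Panel intervals are
half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon, box

from ._errors import PanelSelectionError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class CellPolygon:
    """A traced cell outline with (optionally) its nucleus outline."""

    cell_id: int
    cell: Polygon
    nucleus: Polygon | None = None
    region: str | None = None
    clipped: bool = False

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.cell.centroid
        return (c.x, c.y)

    @property
    def cell_area(self) -> float:
        return polygon_area(np.asarray(self.cell.exterior.coords)[:-1])

    @property
    def nucleus_area(self) -> float | None:
        if self.nucleus is None:
            return None
        return polygon_area(np.asarray(self.nucleus.exterior.coords)[:-1])


@dataclass
class TemPanel:
    """One stitched-TEM panel: an axis interval of the strip."""

    panel_id: int
    x_start_um: float
    x_end_um: float
    y_start_um: float = 0.0
    y_end_um: float = 0.0
    contains_spheroid_edge: bool = False
    raster: np.ndarray | None = field(default=None, repr=False)
    resolution_px_per_um: float | None = None

    def __post_init__(self) -> None:
        if self.x_start_um >= self.x_end_um:
            raise ValidationError("panel must have x_start < x_end")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x_start_um, self.y_start_um, self.x_end_um, self.y_end_um)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.x_start_um + self.x_end_um)

    @property
    def geometry(self):
        return box(*self.bounds)


@dataclass(frozen=True)
class RegionPartition:
    """Inner-50% / outer-25%+25% split of the primary-axis extent."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max:
            raise ValidationError("extent must have x_min < x_max")

    @property
    def length(self) -> float:
        return self.x_max - self.x_min

    @property
    def inner_interval(self) -> tuple[float, float]:
        return (self.x_min + 0.25 * self.length, self.x_min + 0.75 * self.length)

    def label(self, x: float) -> str:
        """Region of an axis coordinate: half-open inner interval, boundary → inner."""
        if not self.x_min <= x <= self.x_max:
            raise ValidationError(f"centroid x={x:g} outside extent "
                                  f"[{self.x_min:g}, {self.x_max:g}]")
        lo, hi = self.inner_interval
        return "inner" if lo <= x < hi else "outer"


def polygon_area(vertices) -> float:
    """Shoelace area (μm²) of a simple polygon, orientation independent."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValidationError("need >= 3 (x, y) vertices")
    poly = Polygon(v)
    if not poly.is_valid:
        raise ValidationError("polygon is self-intersecting or degenerate")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def is_complete_cell(cell: CellPolygon, panel: TemPanel) -> bool:
    """Whether the cell shows its entire rim and whole nucleus inside the panel.

    True iff the cell outline lies strictly inside the panel rectangle
    (touching the boundary disqualifies) and a nucleus outline exists and
    lies fully inside the cell outline.
    """
    panel_box = panel.geometry
    if not shapely.contains_properly(panel_box, cell.cell):
        return False
    if cell.nucleus is None:
        return False
    return bool(cell.cell.covers(cell.nucleus))


def partition_regions(cells, extent: tuple[float, float]) -> list[str]:
    """Label each cell 'inner'/'outer' by its centroid's axis coordinate."""
    part = RegionPartition(*extent)
    return [part.label(c.centroid[0]) for c in cells]


def select_density_panels(panels) -> tuple[TemPanel, tuple[TemPanel, TemPanel]]:
    """Pick the center panel and the outermost edge-free panel on each side.

    Center = panel whose midpoint is closest to the extent midpoint (ties
    to the lower panel id).  Outer = on each side of the center, the
    outermost panel whose interval does not include the spheroid edge.
    """
    panels = sorted(panels, key=lambda p: p.panel_id)
    if len(panels) < 3:
        raise PanelSelectionError("either")
    x_min = min(p.x_start_um for p in panels)
    x_max = max(p.x_end_um for p in panels)
    mid = 0.5 * (x_min + x_max)
    center = min(panels, key=lambda p: (abs(p.midpoint - mid), p.panel_id))
    left = [p for p in panels if p.midpoint < center.midpoint
            and not p.contains_spheroid_edge]
    right = [p for p in panels if p.midpoint > center.midpoint
             and not p.contains_spheroid_edge]
    if not left:
        raise PanelSelectionError("left")
    if not right:
        raise PanelSelectionError("right")
    outer_left = min(left, key=lambda p: p.midpoint)
    outer_right = max(right, key=lambda p: p.midpoint)
    return center, (outer_left, outer_right)


def _cover_mask(geometries, bounds: tuple[float, float, float, float],
                resolution: float) -> np.ndarray:
    """Boolean mask of pixels (centers) covered by any geometry.

    Pixel-center point sampling keeps thin interstitial gaps unbiased: a
    pixel counts as covered iff its center lies inside a filled outline.
    """
    x0, y0, x1, y1 = bounds
    nx = max(1, int(round((x1 - x0) * resolution)))
    ny = max(1, int(round((y1 - y0) * resolution)))
    xs = x0 + (np.arange(nx) + 0.5) / resolution
    ys = y0 + (np.arange(ny) + 0.5) / resolution
    mask = np.zeros((ny, nx), dtype=bool)
    for geom in geometries:
        if geom.is_empty:
            continue
        polys = getattr(geom, "geoms", [geom])
        for poly in polys:
            if poly.is_empty or poly.area == 0:
                continue
            gx0, gy0, gx1, gy1 = poly.bounds
            ix = np.nonzero((xs >= gx0) & (xs <= gx1))[0]
            iy = np.nonzero((ys >= gy0) & (ys <= gy1))[0]
            if ix.size == 0 or iy.size == 0:
                continue
            gx, gy = np.meshgrid(xs[ix], ys[iy])
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            path = _MplPath(np.asarray(poly.exterior.coords))
            inside = path.contains_points(pts).reshape(gy.shape)
            for interior in poly.interiors:
                hole = _MplPath(np.asarray(interior.coords))
                inside &= ~hole.contains_points(pts).reshape(gy.shape)
            mask[np.ix_(iy, ix)] |= inside
    return mask


def intercellular_space_density(panel: TemPanel, cells, resolution: float = 2.0
                                ) -> float:
    """Uncovered-area percentage of a panel after filling cell outlines.

    Cell outlines are clipped to the panel, filled, and rasterized at
    ``resolution`` px/μm over the full panel; the density is
    100 × (pixels not covered by any cell) / (total pixels).
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    panel_box = panel.geometry
    geoms = [c.cell.intersection(panel_box) for c in cells
             if c.cell.intersects(panel_box)]
    if not geoms:
        log.warning("panel %s contains no cells; density = 100%%", panel.panel_id)
        return 100.0
    mask = _cover_mask(geoms, panel.bounds, resolution)
    return 100.0 * float((~mask).sum()) / mask.size


def complete_cells_in_panels(cells, panels) -> list[CellPolygon]:
    """Cells complete in at least one panel, unique by cell_id."""
    seen: dict[int, CellPolygon] = {}
    for panel in panels:
        for cell in cells:
            if cell.cell_id not in seen and is_complete_cell(cell, panel):
                seen[cell.cell_id] = cell
    return [seen[k] for k in sorted(seen)]


@dataclass(frozen=True)
class MorphometrySummary:
    """Group-level morphometry: area statistics and space densities.

    ``areas``: one row per (group, region) with pooled mean/SD (ddof=1)
    of complete-cell and nucleus areas and the cell count N.  ``densities``:
    one row per (group, region) with the mean ± SD over spheroids of the
    intercellular-space density (%), region meaning center vs outer panels.
    """

    areas: pd.DataFrame
    densities: pd.DataFrame


def summarize_groups(cell_records: pd.DataFrame,
                     density_records: pd.DataFrame | None = None
                     ) -> MorphometrySummary:
    """Aggregate per-cell areas and per-spheroid densities into group stats.

    ``cell_records`` columns: group, region, cell_area_um2, nucleus_area_um2
    (complete cells only, pooled across spheroids).  ``density_records``
    columns: group, spheroid, region, density_pct.  Groups with fewer than
    2 observations report SD as NaN.
    """
    required = {"group", "region", "cell_area_um2", "nucleus_area_um2"}
    if not required.issubset(cell_records.columns):
        raise ValidationError(f"cell_records must have columns {sorted(required)}")

    def _agg(df: pd.DataFrame, col: str) -> pd.Series:
        n = len(df)
        return pd.Series({
            f"{col.split('_')[0]}_mean": df[col].mean(),
            f"{col.split('_')[0]}_sd": df[col].std(ddof=1) if n >= 2 else np.nan,
        })

    rows = []
    for (group, region), df in sorted(cell_records.groupby(["group", "region"])):
        row = {"group": group, "region": region, "n_cells": len(df)}
        row.update(_agg(df, "cell_area_um2"))
        row.update(_agg(df, "nucleus_area_um2"))
        rows.append(row)
    areas = pd.DataFrame(rows)

    if density_records is not None and len(density_records):
        drows = []
        for (group, region), df in sorted(density_records.groupby(["group", "region"])):
            per_spheroid = df.groupby("spheroid")["density_pct"].mean()
            drows.append({
                "group": group, "region": region,
                "density_mean": per_spheroid.mean(),
                "density_sd": per_spheroid.std(ddof=1) if len(per_spheroid) >= 2 else np.nan,
                "n_spheroids": len(per_spheroid),
            })
        densities = pd.DataFrame(drows)
    else:
        densities = pd.DataFrame(
            columns=["group", "region", "density_mean", "density_sd", "n_spheroids"])
    return MorphometrySummary(areas=areas, densities=densities)
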