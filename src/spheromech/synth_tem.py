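"""Synthetic TEM strips: seeded polygonal cell tessellations.

Stands in for the stitched TEM micrographs: a rectangular strip spanning
the spheroid's primary axis is tiled with polygonal cells (each with a
nucleus), with the interstitial space between cells calibrated per region
to a target uncovered-area fraction.

Construction
------------
1.  Target cell areas are drawn from a lognormal matched by moments to the
    preset mean/SD (areas are positive and right-skewed); cell counts per
    region are set so coverage × mean area fills the region.
2.  Seed points are dart-thrown with exclusion radii proportional to
    sqrt(drawn area), so larger draws claim proportionally larger
    territories.  The repulsion strength is set per region from the
    preset's area coefficient of variation through a fixed calibration
    curve (no repulsion reproduces the Poisson-Voronoi CV of ~0.52;
    stronger repulsion regularizes the mosaic and lowers the CV).
3.  A bounded Voronoi diagram (mirror-point trick: the point set is
    reflected across each strip wall, making every interior cell finite
    and exactly clipped) assigns each seed its territory.
4.  Each cell is its Voronoi territory shrunk toward its centroid by a
    region-uniform factor (disjointness by construction), bisected so the
    polygon-exact uncovered fraction of the region's territory equals the
    preset space density.  A uniform factor keeps the interstitial space
    evenly distributed, which is what the micrographs show; cell-size
    dispersion is carried by the territory distribution itself.
5.  Gap styles: "uniform" keeps a constant rim offset; "beaded" modulates
    the rim offset sinusoidally along the boundary, imitating the
    bead-shaped interstitial spaces between adjacent cells.
6.  The nucleus is the cell polygon rescaled about its centroid to the
    nucleus/cell area ratio drawn from the nucleus-area preset — strictly
    inside its cell by construction.

Panels: the strip is cut into consecutive axis intervals with 10%
overlap; polygons are clipped per panel, with a flag marking clipping, and
panels can be rendered to grayscale rasters (light gaps, darker cell
interiors, darkest nuclei).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from ._errors import ValidationError
from .morphometry import CellPolygon, TemPanel, _cover_mask
from .specs import TemRegionPreset

log = logging.getLogger(__name__)

#: Relative amplitude of the beaded gap modulation (gap oscillates between
#: (1-β) and (1+β) times its mean width along the boundary).
_BEAD_AMPLITUDE = 0.85
#: Approximate bead spacing along the cell boundary (μm).
_BEAD_SPACING_UM = 6.0

#: Calibration curve mapping realized area CV to dart-throw repulsion
#: strength (measured once on this generator at the study strip size).
_CV_ANCHORS = np.array([0.315, 0.42, 0.49, 0.52])
_SPACING_ANCHORS = np.array([0.55, 0.40, 0.25, 0.0])


def _spacing_for_cv(cv: float) -> float:
    """Repulsion strength reproducing a target Voronoi-area CV."""
    return float(np.interp(cv, _CV_ANCHORS, _SPACING_ANCHORS))


@dataclass(frozen=True)
class TemStrip:
    """A generated strip: geometry plus per-cell ground truth."""

    length_um: float
    height_um: float
    cells: list[CellPolygon]
    seed: int


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _dart_throw(rng: np.random.Generator, radii: np.ndarray, spacing: np.ndarray,
                windows, weights, attempts: int = 60) -> np.ndarray:
    """Place points with soft minimum separation s_i·r_i + s_j·r_j.

    ``spacing`` is the per-point repulsion strength.  Larger radii are
    placed first; if no candidate satisfies the separation after
    ``attempts`` tries, the best (most separated) candidate is kept so the
    requested count is always met.
    """
    order = np.argsort(radii)[::-1]
    placed = np.empty((len(radii), 2))
    placed_sr = np.empty(len(radii))  # spacing * radius per placed point
    n_placed = 0
    for idx in order:
        sr = spacing[idx] * radii[idx]
        best, best_score = None, -np.inf
        for _ in range(attempts):
            w = windows[rng.choice(len(windows), p=weights[idx])]
            cand = np.array([rng.uniform(w[0], w[2]), rng.uniform(w[1], w[3])])
            if n_placed == 0:
                best, best_score = cand, np.inf
                break
            d = np.hypot(*(placed[:n_placed] - cand).T)
            min_sep = placed_sr[:n_placed] + sr
            if np.all(min_sep <= 0):
                best, best_score = cand, np.inf
                break
            score = float(np.min(d / np.maximum(min_sep, 1e-9)))
            if score > best_score:
                best, best_score = cand, score
            if score >= 1.0:
                break
        placed[n_placed] = best
        placed_sr[n_placed] = sr
        n_placed += 1
    out = np.empty_like(placed)
    out[order] = placed  # restore draw order
    return out


def _bounded_voronoi(points: np.ndarray, length: float, height: float
                     ) -> list[np.ndarray]:
    """Voronoi cells clipped exactly to [0, L]×[0, H] via mirrored points."""
    mirrors = [
        points * np.array([-1.0, 1.0]),
        np.column_stack([2.0 * length - points[:, 0], points[:, 1]]),
        points * np.array([1.0, -1.0]),
        np.column_stack([points[:, 0], 2.0 * height - points[:, 1]]),
    ]
    vor = Voronoi(np.vstack([points] + mirrors))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        center = verts.mean(axis=0)
        angles = np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0])
        cells.append(verts[np.argsort(angles)])
    return cells


def _shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _centroid(verts: np.ndarray) -> np.ndarray:
    x, y = verts[:, 0], verts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    area6 = 3.0 * np.sum(cross)
    cx = np.sum((x + np.roll(x, -1)) * cross) / area6
    cy = np.sum((y + np.roll(y, -1)) * cross) / area6
    return np.array([cx, cy])


def _densify(verts: np.ndarray, step: float) -> np.ndarray:
    out = []
    for a, b in zip(verts, np.roll(verts, -1, axis=0)):
        seg = b - a
        n = max(1, int(np.ceil(np.hypot(*seg) / step)))
        for k in range(n):
            out.append(a + seg * (k / n))
    return np.asarray(out)


class _CellBlueprint:
    """Precomputed geometry for one cell, evaluated at a global shrink G."""

    def __init__(self, verts: np.ndarray, target_area: float, gap_style: str,
                 rng: np.random.Generator, densify_step: float = 1.2):
        self.voronoi_area = _shoelace(verts)
        self.center = _centroid(verts)
        dense = _densify(verts, densify_step)
        self.rel = dense - self.center
        seg = np.hypot(*(np.roll(dense, -1, axis=0) - dense).T)
        perimeter = float(seg.sum())
        arc = np.concatenate([[0.0], np.cumsum(seg[:-1])]) / perimeter
        n_lobes = max(3, int(round(perimeter / _BEAD_SPACING_UM)))
        self.phase_term = 2.0 * np.pi * n_lobes * arc + rng.uniform(0, 2 * np.pi)
        self.target_area = target_area
        self.gap_style = gap_style

    def scale(self, g: float) -> float:
        return min(1.0, g)

    def radial_factor(self, g: float) -> np.ndarray:
        s = self.scale(g)
        if self.gap_style == "uniform" or s <= 0.05:
            return np.full(len(self.rel), s)
        beta = min(_BEAD_AMPLITUDE, 0.95 / (1.0 - s) - 1.0) if s < 1.0 else 0.0
        return 1.0 - (1.0 - s) * (1.0 + beta * np.sin(self.phase_term))

    def vertices(self, g: float) -> np.ndarray:
        return self.center + self.rel * self.radial_factor(g)[:, None]

    def area(self, g: float) -> float:
        return _shoelace(self.vertices(g))


def _calibrate_shrink(blueprints: list[_CellBlueprint], target_density: float,
                      tol: float = 1e-4, max_iter: int = 60) -> float:
    """Bisect the global shrink so 1 - Σarea/Σterritory = target_density."""
    territory = sum(b.voronoi_area for b in blueprints)

    def uncovered(g: float) -> float:
        return 1.0 - sum(b.area(g) for b in blueprints) / territory

    lo, hi = 0.05, 1.0 + 1e-9
    if uncovered(lo) < target_density:
        lo = 1e-3
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        u = uncovered(mid)
        if abs(u - target_density) < tol:
            return mid
        if u > target_density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_cell_tessellation(strip_length_um: float, strip_height_um: float,
                             presets: dict[str, TemRegionPreset], seed: int = 0
                             ) -> TemStrip:
    """Generate a seeded cell tessellation of the strip.

    ``presets`` maps 'inner' and 'outer' to their region presets; the inner
    preset governs the central 50% of the strip length, the outer preset
    the two flanking 25% slabs.  Region labels on the returned cells record
    the region each seed point was sampled in (ground truth).
    """
    if strip_length_um <= 0 or strip_height_um <= 0:
        raise ValidationError("strip dimensions must be positive")
    if set(presets) != {"inner", "outer"}:
        raise ValidationError("presets must be given for 'inner' and 'outer'")
    rng = np.random.default_rng(seed)
    length, height = strip_length_um, strip_height_um

    region_windows = {
        "inner": [(0.25 * length, 0.0, 0.75 * length, height)],
        "outer": [(0.0, 0.0, 0.25 * length, height),
                  (0.75 * length, 0.0, length, height)],
    }

    areas, regions, weights, spacings = [], [], [], []
    all_windows, window_region = [], []
    for region, wins in region_windows.items():
        all_windows.extend(wins)
        window_region.extend([region] * len(wins))
    for region in ("inner", "outer"):
        preset = presets[region]
        region_area = sum((w[2] - w[0]) * (w[3] - w[1]) for w in region_windows[region])
        n_cells = max(3, int(round(
            region_area * (1.0 - preset.target_space_density) / preset.cell_area_mean)))
        mu, sigma = _lognormal_params(preset.cell_area_mean, preset.cell_area_sd)
        drawn = rng.lognormal(mu, sigma, size=n_cells)
        areas.append(drawn)
        regions.extend([region] * n_cells)
        spacings.extend([_spacing_for_cv(preset.cell_area_sd / preset.cell_area_mean)]
                        * n_cells)
        w = np.array([
            ((win[2] - win[0]) * (win[3] - win[1]) if window_region[k] == region else 0.0)
            for k, win in enumerate(all_windows)])
        weights.extend([w / w.sum()] * n_cells)

    target_areas = np.concatenate(areas)
    radii = np.sqrt(target_areas / np.pi)
    points = _dart_throw(rng, radii, np.asarray(spacings), all_windows, weights)
    voronoi_cells = _bounded_voronoi(points, length, height)

    blueprints = [
        _CellBlueprint(verts, target_areas[i], presets[regions[i]].gap_style, rng)
        for i, verts in enumerate(voronoi_cells)
    ]
    shrink = {}
    for region in ("inner", "outer"):
        group = [b for b, r in zip(blueprints, regions) if r == region]
        shrink[region] = _calibrate_shrink(group, presets[region].target_space_density)

    cells = []
    for i, bp in enumerate(blueprints):
        region = regions[i]
        verts = bp.vertices(shrink[region])
        cell_poly = Polygon(verts)
        if not cell_poly.is_valid:
            cell_poly = cell_poly.buffer(0)
        cell_area = cell_poly.area
        preset = presets[region]
        mu_n, sigma_n = _lognormal_params(preset.nucleus_area_mean, preset.nucleus_area_sd)
        nucleus_area = rng.lognormal(mu_n, sigma_n)
        ratio = float(np.clip(nucleus_area / cell_area, 0.04, 0.80))
        nuc_verts = bp.center + (verts - bp.center) * np.sqrt(ratio)
        nucleus = Polygon(nuc_verts)
        if not nucleus.is_valid:
            nucleus = nucleus.buffer(0)
        cells.append(CellPolygon(cell_id=i, cell=cell_poly, nucleus=nucleus,
                                 region=region, clipped=False))
    return TemStrip(length_um=length, height_um=height, cells=cells, seed=seed)


def panel_layout(strip_length_um: float, panel_width_um: float,
                 overlap_frac: float = 0.1) -> list[tuple[float, float]]:
    """Consecutive overlapping panel intervals covering [0, strip_length]."""
    if panel_width_um > strip_length_um:
        raise ValidationError("panel width must not exceed the strip length")
    step = panel_width_um * (1.0 - overlap_frac)
    starts = [0.0]
    while starts[-1] + step + panel_width_um <= strip_length_um:
        starts.append(starts[-1] + step)
    if starts[-1] + panel_width_um < strip_length_um - 1e-9:
        starts.append(strip_length_um - panel_width_um)
    return [(s, s + panel_width_um) for s in starts]


def render_tem_panels(strip: TemStrip, panel_width_um: float = 60.0,
                      overlap_frac: float = 0.1, resolution_px_per_um: float = 2.0,
                      render: bool = True
                      ) -> tuple[list[TemPanel], list[list[CellPolygon]]]:
    """Cut the strip into overlapping panels; clip polygons; optionally render.

    Returns ``(panels, cells_per_panel)`` where each panel's cell list
    holds the polygons clipped to that panel, with ``clipped`` flagging
    cells that touch or cross the panel boundary.  Rendering paints light
    interstitial gaps (0.92), darker cell interiors (0.55) and darkest
    nuclei (0.25) at the stated resolution.
    """
    min_gap_um = 1.0 / (2.0 * resolution_px_per_um)
    if min_gap_um > 1.0:
        log.warning("resolution %.2f px/μm may not resolve sub-μm gaps",
                    resolution_px_per_um)
    intervals = panel_layout(strip.length_um, panel_width_um, overlap_frac)
    panels: list[TemPanel] = []
    cells_per_panel: list[list[CellPolygon]] = []
    for pid, (x0, x1) in enumerate(intervals):
        edge = x0 <= 1e-9 or x1 >= strip.length_um - 1e-9
        panel = TemPanel(panel_id=pid, x_start_um=x0, x_end_um=x1,
                         y_start_um=0.0, y_end_um=strip.height_um,
                         contains_spheroid_edge=edge,
                         resolution_px_per_um=resolution_px_per_um)
        panel_box = panel.geometry
        clipped_cells: list[CellPolygon] = []
        for cell in strip.cells:
            if not cell.cell.intersects(panel_box):
                continue
            inside = shapely.contains_properly(panel_box, cell.cell)
            geom = cell.cell if inside else cell.cell.intersection(panel_box)
            nuc = cell.nucleus
            if nuc is not None and not inside:
                nuc = nuc.intersection(panel_box)
                nuc = nuc if (not nuc.is_empty and nuc.geom_type == "Polygon") else None
            if geom.is_empty or geom.geom_type not in ("Polygon", "MultiPolygon"):
                continue
            if geom.geom_type == "MultiPolygon":
                geom = max(geom.geoms, key=lambda g: g.area)
            clipped_cells.append(CellPolygon(
                cell_id=cell.cell_id, cell=geom, nucleus=nuc,
                region=cell.region, clipped=not inside))
        if render:
            raster = np.full(
                (max(1, int(round(strip.height_um * resolution_px_per_um))),
                 max(1, int(round(panel_width_um * resolution_px_per_um)))), 0.92)
            cell_mask = _cover_mask([c.cell for c in clipped_cells], panel.bounds,
                                    resolution_px_per_um)
            nuc_mask = _cover_mask([c.nucleus for c in clipped_cells
                                    if c.nucleus is not None], panel.bounds,
                                   resolution_px_per_um)
            raster[cell_mask] = 0.55
            raster[nuc_mask] = 0.25
            panel.raster = raster
        panels.append(panel)
        cells_per_panel.append(clipped_cells)
    return panels, cells_per_panel
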