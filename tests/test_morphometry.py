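"""Morphometry protocol: areas, filtering, partition, density, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from spheromech import (
    CellPolygon,
    PanelSelectionError,
    RegionPartition,
    TemPanel,
    ValidationError,
    complete_cells_in_panels,
    intercellular_space_density,
    is_complete_cell,
    partition_regions,
    polygon_area,
    select_density_panels,
    summarize_groups,
)
from spheromech.morphometry import _cover_mask


def _random_convex_polygon(rng, scale=20.0):
    n = rng.integers(4, 12)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.3, 1.0, n) * scale
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0

    def test_triangle(self):
        assert polygon_area([(0, 0), (2, 0), (0, 2)]) == 2.0

    def test_orientation_independent(self):
        cw = [(0, 0), (0, 1), (1, 1), (1, 0)]
        assert polygon_area(cw) == 1.0

    def test_self_intersection_rejected(self):
        with pytest.raises(ValidationError):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie

    def test_matches_rasterization_oracle(self, rng):
        """Shoelace area vs pixel counting at high resolution, 100 polygons."""
        for _ in range(100):
            pts = _random_convex_polygon(rng)
            hull = Polygon(pts).convex_hull
            verts = np.asarray(hull.exterior.coords)[:-1]
            exact = polygon_area(verts)
            res = 20.0  # px per unit length
            mask = _cover_mask([hull], hull.bounds, res)
            raster = mask.sum() / res**2
            assert abs(raster - exact) / exact < 0.005

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_shapely_on_random_convex_polygons(self, seed):
        rng = np.random.default_rng(seed)
        hull = Polygon(_random_convex_polygon(rng)).convex_hull
        verts = np.asarray(hull.exterior.coords)[:-1]
        assert polygon_area(verts) == pytest.approx(hull.area, rel=1e-12)


def _make_panel(x0=0.0, x1=100.0, y1=100.0, pid=0, edge=False):
    return TemPanel(panel_id=pid, x_start_um=x0, x_end_um=x1,
                    y_start_um=0.0, y_end_um=y1, contains_spheroid_edge=edge)


def _cell(poly, nucleus=None, cid=0):
    return CellPolygon(cell_id=cid, cell=poly, nucleus=nucleus)


class TestCompleteCell:
    def test_interior_cell_with_nucleus_is_complete(self):
        cell = _cell(box(10, 10, 30, 30), nucleus=box(15, 15, 25, 25))
        assert is_complete_cell(cell, _make_panel())

    def test_cell_touching_panel_boundary_is_incomplete(self):
        cell = _cell(box(0, 10, 20, 30), nucleus=box(5, 15, 15, 25))
        assert not is_complete_cell(cell, _make_panel())

    def test_missing_nucleus_is_incomplete(self):
        assert not is_complete_cell(_cell(box(10, 10, 30, 30)), _make_panel())

    def test_synthetic_complete_count_equals_unclipped(self, day5_strip):
        """The filter reproduces the generator's unclipped-cell ground truth."""
        strip, panels, cells_per_panel = day5_strip
        complete = complete_cells_in_panels(strip.cells, panels)
        unclipped_ids = set()
        for cells in cells_per_panel:
            unclipped_ids |= {c.cell_id for c in cells if not c.clipped}
        assert {c.cell_id for c in complete} == unclipped_ids


class TestPartition:
    def test_labels(self):
        part = RegionPartition(0.0, 100.0)
        assert part.label(10.0) == "outer"
        assert part.label(50.0) == "inner"
        assert part.label(25.0) == "inner"  # boundary tie-break
        assert part.label(75.0) == "outer"  # half-open upper bound

    def test_centroid_outside_extent_raises(self):
        with pytest.raises(ValidationError):
            RegionPartition(0.0, 100.0).label(101.0)

    def test_partition_is_exhaustive(self, day20_strip_full):
        labels = day20_strip_full.cell_records["region"]
        assert set(labels) <= {"inner", "outer"}
        assert len(labels) == len(day20_strip_full.cell_records)


class TestSelectDensityPanels:
    def _five_panels(self, edge_flags):
        return [_make_panel(x0=i * 80.0, x1=(i + 1) * 80.0, pid=i + 1, edge=e)
                for i, e in enumerate(edge_flags)]

    def test_center_and_outer_selection(self):
        panels = self._five_panels([True, False, False, False, True])
        center, (left, right) = select_density_panels(panels)
        assert center.panel_id == 3
        assert (left.panel_id, right.panel_id) == (2, 4)

    def test_all_edge_flagged_raises(self):
        panels = self._five_panels([True] * 5)
        with pytest.raises(PanelSelectionError):
            select_density_panels(panels)

    def test_synthetic_outer_panels_are_second_to_outermost(self, day5_strip):
        _, panels, _ = day5_strip
        center, (left, right) = select_density_panels(panels)
        assert left.panel_id == 1
        assert right.panel_id == len(panels) - 2
        assert not center.contains_spheroid_edge


class TestSpaceDensity:
    def test_fully_tiled_panel_is_zero(self):
        panel = _make_panel(0, 40, 40)
        cells = [_cell(box(0, 0, 40, 20), cid=0), _cell(box(0, 20, 40, 40), cid=1)]
        assert intercellular_space_density(panel, cells, 2.0) == 0.0

    def test_half_covered_panel_is_fifty_percent(self):
        panel = _make_panel(0, 40, 40)
        cells = [_cell(box(0, 0, 40, 10), cid=0), _cell(box(0, 30, 40, 40), cid=1)]
        assert intercellular_space_density(panel, cells, 2.0) == 50.0

    def test_empty_panel_warns_hundred_percent(self, caplog):
        with caplog.at_level("WARNING"):
            density = intercellular_space_density(_make_panel(), [], 2.0)
        assert density == 100.0

    def test_density_plus_covered_is_exactly_hundred(self, day5_strip):
        strip, panels, _ = day5_strip
        panel = panels[1]
        density = intercellular_space_density(panel, strip.cells, 2.0)
        geoms = [c.cell.intersection(panel.geometry) for c in strip.cells
                 if c.cell.intersects(panel.geometry)]
        mask = _cover_mask(geoms, panel.bounds, 2.0)
        covered = 100.0 * mask.sum() / mask.size
        assert density + covered == 100.0

    def test_converges_under_resolution_refinement(self, day5_strip):
        """Doubling the raster resolution moves the density by <0.2 pp."""
        strip, panels, _ = day5_strip
        panel = panels[2]
        d4 = intercellular_space_density(panel, strip.cells, 4.0)
        d8 = intercellular_space_density(panel, strip.cells, 8.0)
        assert abs(d8 - d4) < 0.2


class TestSummarize:
    def test_single_group(self):
        records = pd.DataFrame({
            "group": "g", "region": "inner",
            "cell_area_um2": [4.0, 4.0, 4.0], "nucleus_area_um2": [1.0, 1.0, 1.0]})
        summary = summarize_groups(records)
        row = summary.areas.iloc[0]
        assert (row["cell_mean"], row["cell_sd"], row["n_cells"]) == (4.0, 0.0, 3)

    def test_permutation_invariance(self, day20_strip_full, rng):
        records = day20_strip_full.cell_records
        shuffled = records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = summarize_groups(records).areas
        b = summarize_groups(shuffled).areas
        pd.testing.assert_frame_equal(a, b)

    def test_small_group_sd_is_nan(self):
        records = pd.DataFrame({
            "group": "g", "region": "inner",
            "cell_area_um2": [4.0], "nucleus_area_um2": [1.0]})
        summary = summarize_groups(records)
        assert np.isnan(summary.areas.iloc[0]["cell_sd"])

    def test_density_aggregation_over_spheroids(self):
        density = pd.DataFrame([
            {"group": "g", "spheroid": s, "region": "inner", "density_pct": d}
            for s, d in enumerate([2.0, 3.0, 4.0])])
        records = pd.DataFrame({
            "group": "g", "region": "inner",
            "cell_area_um2": [4.0, 5.0], "nucleus_area_um2": [1.0, 2.0]})
        summary = summarize_groups(records, density)
        row = summary.densities.iloc[0]
        assert row["density_mean"] == 3.0
        assert row["n_spheroids"] == 3
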