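"""Predictor layers: distances, terrain derivatives, kriging, habitat."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, Polygon, box

from coastsdm.effort import EffortMap, select_absences
from coastsdm.grid import GridSpec
from coastsdm.layers import (
    MissingValueError,
    PredictorLayer,
    SphericalVariogram,
    assemble_feature_table,
    cost_distance_layer,
    euclidean_distance_layer,
    grid_feature_frame,
    krige_layer,
    ordinary_kriging_weights,
    sample_categorical,
    slope_complexity_layers,
)

from oracles import dijkstra_lattice, kriging_system_solve


def open_grid(n=6, cell=500.0, marine=None):
    mask = np.ones((n, n), dtype=bool) if marine is None else marine
    return GridSpec(origin=(0.0, 0.0), cell_size_m=cell, n_rows=mask.shape[0],
                    n_cols=mask.shape[1], marine_mask=mask)


class TestEuclideanDistance:
    def test_point_to_straight_coastline(self):
        grid = open_grid(3)
        coast = LineString([(-10_000, 50.0), (10_000, 50.0)])
        layer = euclidean_distance_layer(grid, coast)
        # row 1 centroids are at y=750 -> 700 m north of the line
        assert layer.values[1, 1] == pytest.approx(700.0)

    def test_zero_inside_target_polygon(self):
        grid = open_grid(2)
        layer = euclidean_distance_layer(grid, box(0, 0, 1_000, 1_000))
        assert layer.values[0, 0] == 0.0
        assert layer.values[1, 1] == 0.0

    def test_zero_on_cells_intersecting_target(self):
        grid = open_grid(2)
        line = LineString([(10.0, 10.0), (90.0, 10.0)])  # inside cell (0,0) only
        layer = euclidean_distance_layer(grid, line)
        assert layer.values[0, 0] == 0.0
        assert layer.values[1, 1] > 0

    def test_matches_densified_vertex_oracle(self):
        rng = np.random.default_rng(2)
        grid = open_grid(20, cell=100.0)
        xs = np.linspace(-100, 2_100, 23)
        ys = rng.uniform(-400, -50, size=xs.shape)
        coast = LineString(np.column_stack([xs, ys]))
        layer = euclidean_distance_layer(grid, coast)
        # densify the polyline at 1 m and take the minimum vertex distance
        dense = [
            coast.interpolate(d) for d in np.arange(0, coast.length, 1.0)
        ]
        dense_xy = np.array([[p.x, p.y] for p in dense])
        rows, cols = np.nonzero(grid.marine_mask)
        for r, c in list(zip(rows, cols))[::37]:
            cx, cy = grid.cell_center(r, c)
            brute = np.min(np.hypot(dense_xy[:, 0] - cx, dense_xy[:, 1] - cy))
            assert abs(layer.values[r, c] - brute) <= 1.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance_layer(open_grid(2), Polygon())


class TestCostDistance:
    def test_target_cell_is_zero(self):
        grid = open_grid(5)
        layer = cost_distance_layer(grid, Point(250.0, 250.0))
        assert layer.values[0, 0] == 0.0

    def test_open_water_close_to_euclidean(self):
        grid = open_grid(9)
        target = Point(250.0, 250.0)
        cost = cost_distance_layer(grid, target)
        euclid = euclidean_distance_layer(grid, target)
        rows, cols = np.nonzero(grid.marine_mask)
        c = cost.values[rows, cols]
        e = euclid.values[rows, cols]
        assert np.all(c >= e - 1e-9)
        # 8-connected lattice metric overestimates by at most ~8.3 %
        assert np.all(c <= 1.083 * e + grid.cell_size_m * np.sqrt(2) + 1e-9)
        # exact along the axes
        assert cost.values[0, 4] == pytest.approx(4 * 500.0)

    def test_u_shaped_barrier_matches_dijkstra_oracle(self):
        mask = np.ones((9, 9), dtype=bool)
        mask[0:7, 4] = False  # peninsula wall, open only at the top
        grid = open_grid(marine=mask)
        target = Point(250.0, 250.0)
        layer = cost_distance_layer(grid, target)
        oracle = dijkstra_lattice(mask, [(0, 0)], 500.0)
        assert np.allclose(layer.values[mask], oracle[mask])
        # the wall forces a detour beyond straight-line distance
        e = euclidean_distance_layer(grid, target)
        assert layer.values[0, 8] > e.values[0, 8] + 500.0

    def test_cost_at_least_euclidean_on_survey(self, study_area, all_layers):
        """Around-land distance never undercuts the straight-line distance
        (up to half a cell diagonal of lattice discretisation)."""
        by_name = {l.name: l for l in all_layers}
        m = study_area.grid.marine_mask
        slack = study_area.grid.cell_size_m * np.sqrt(2) / 2
        for name, target in [
            ("dist_reef_m", study_area.reef_crest),
            ("dist_ramp_m", study_area.boat_ramps[0].union(study_area.boat_ramps[1])),
        ]:
            euclid = euclidean_distance_layer(study_area.grid, target)
            cost = by_name[name].values[m]
            assert np.all(cost >= euclid.values[m] - slack)

    def test_unreachable_cells_flagged(self):
        mask = np.ones((3, 3), dtype=bool)
        mask[:, 1] = False  # split into two components
        grid = open_grid(marine=mask)
        layer = cost_distance_layer(grid, Point(250.0, 250.0))
        assert np.isinf(layer.values[:, 2]).all()


class TestSlopeComplexity:
    def test_constant_depth(self):
        grid = open_grid(4)
        depth = np.full((4, 4), 12.0)
        slope, complexity = slope_complexity_layers(depth, grid)
        assert np.allclose(slope.values, 0.0)
        assert np.allclose(complexity.values, 0.0)

    def test_planar_ramp_slope(self):
        grid = open_grid(5)
        cols = np.arange(5)
        depth = np.tile(cols * 1.0, (5, 1))  # 1 m per 500 m eastwards
        slope, _ = slope_complexity_layers(depth, grid)
        expected = np.degrees(np.arctan(1.0 / 500.0))
        assert slope.values[2, 2] == pytest.approx(expected)

    def test_isolated_cell(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        grid = open_grid(marine=mask)
        depth = np.where(mask, 5.0, np.nan)
        slope, complexity = slope_complexity_layers(depth, grid)
        assert slope.values[1, 1] == 0.0
        assert complexity.values[1, 1] == 0.0

    def test_random_surface_matches_neighbourhood_recompute(self):
        rng = np.random.default_rng(5)
        grid = open_grid(8)
        depth = rng.uniform(1, 40, size=(8, 8))
        slope, complexity = slope_complexity_layers(depth, grid)
        for r in range(8):
            for c in range(8):
                grads, vals = [], [depth[r, c]]
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) == (0, 0):
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 8 and 0 <= cc < 8:
                            grads.append(
                                abs(depth[rr, cc] - depth[r, c]) / (500 * np.hypot(dr, dc))
                            )
                            vals.append(depth[rr, cc])
                assert slope.values[r, c] == pytest.approx(
                    np.degrees(np.arctan(max(grads)))
                )
                assert complexity.values[r, c] == pytest.approx(np.std(vals))


class TestKriging:
    def test_constant_samples_give_constant_surface(self):
        grid = open_grid(4)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 2_000, size=(8, 2))
        samples = np.column_stack([pts, np.full(8, 3.25)])
        layer = krige_layer(samples, grid, SphericalVariogram(0.0, 1.0, 3_000.0))
        assert np.allclose(layer.values[grid.marine_mask], 3.25)

    def test_exact_at_sample_location_with_zero_nugget(self):
        grid = open_grid(2, cell=1_000.0)
        # put one sample exactly at a cell centre
        samples = np.array([[500.0, 500.0, 7.0], [1_700.0, 1_500.0, 3.0], [100.0, 1_900.0, 5.0]])
        layer = krige_layer(samples, grid, SphericalVariogram(0.0, 2.0, 4_000.0))
        assert layer.values[0, 0] == pytest.approx(7.0, abs=1e-9)

    def test_three_sample_system_matches_direct_solve(self):
        vario = SphericalVariogram(0.1, 1.5, 3_000.0)
        samples_xy = np.array([[0.0, 0.0], [1_000.0, 200.0], [300.0, 1_200.0]])
        values = np.array([4.0, 6.5, 5.2])
        target = (450.0, 400.0)
        expected, w_expected = kriging_system_solve(samples_xy, values, target, vario)
        w = ordinary_kriging_weights(samples_xy, target, vario)
        assert np.allclose(w, w_expected, atol=1e-10)
        assert float(w @ values) == pytest.approx(expected)

    def test_weights_sum_to_one_across_random_configs(self):
        rng = np.random.default_rng(11)
        vario = SphericalVariogram(0.05, 1.0, 2_500.0)
        for _ in range(25):
            k = rng.integers(2, 13)
            xy = rng.uniform(0, 5_000, size=(k, 2))
            w = ordinary_kriging_weights(xy, rng.uniform(0, 5_000, 2), vario)
            assert np.sum(w) == pytest.approx(1.0, abs=1e-8)

    def test_duplicate_samples_averaged(self):
        grid = open_grid(2)
        samples = np.array(
            [[100.0, 100.0, 2.0], [100.0, 100.0, 4.0], [900.0, 900.0, 3.0]]
        )
        layer = krige_layer(samples, grid, SphericalVariogram(0.0, 1.0, 2_000.0))
        assert np.isfinite(layer.values[grid.marine_mask]).all()

    def test_invalid_variogram_rejected(self):
        with pytest.raises(ValueError):
            SphericalVariogram(nugget=2.0, sill=1.0, range_m=100.0)
        with pytest.raises(ValueError):
            SphericalVariogram(range_m=-5.0)


class TestHabitatSampling:
    def test_cell_fully_inside_one_polygon(self):
        grid = open_grid(2)
        layer = sample_categorical([("sand", box(-10, -10, 2_000, 2_000))], grid)
        assert (layer.values[grid.marine_mask] == "sand").all()

    def test_majority_rule_on_split_cell(self):
        grid = open_grid(1)
        polys = [("sand", box(0, 0, 300, 500)), ("reef", box(300, 0, 500, 500))]
        layer = sample_categorical(polys, grid)
        assert layer.values[0, 0] == "sand"

    def test_tie_broken_lexicographically(self):
        grid = open_grid(1)
        polys = [("zoanthid", box(0, 0, 250, 500)), ("algae", box(250, 0, 500, 500))]
        layer = sample_categorical(polys, grid)
        assert layer.values[0, 0] == "algae"

    def test_uncovered_cell_labelled_unclassified(self):
        grid = open_grid(2)
        layer = sample_categorical([("sand", box(0, 0, 490, 490))], grid)
        assert layer.values[1, 1] == "unclassified"

    def test_random_mosaic_matches_rasterization_oracle(self):
        """Majority labels agree with a 10 m rasterisation on >= 99 % of cells."""
        rng = np.random.default_rng(8)
        grid = open_grid(4)
        polys = []
        for i in range(6):
            x0, y0 = rng.uniform(-200, 1_800, 2)
            w, h = rng.uniform(400, 1_500, 2)
            polys.append((f"class{i % 3}", box(x0, y0, x0 + w, y0 + h)))
        layer = sample_categorical(polys, grid)
        from shapely import contains_xy

        agree = total = 0
        sub = (np.arange(50) + 0.5) * 10.0
        sx, sy = np.meshgrid(sub, sub)
        for r in range(4):
            for c in range(4):
                x0, y0, _, _ = grid.cell_bounds(r, c)
                counts = {}
                for lbl, poly in polys:
                    inside = contains_xy(poly, (x0 + sx).ravel(), (y0 + sy).ravel())
                    counts[lbl] = counts.get(lbl, 0) + inside.sum()
                if max(counts.values(), default=0) == 0:
                    expected = "unclassified"
                else:
                    top = max(counts.values())
                    expected = sorted(k for k, v in counts.items() if v == top)[0]
                total += 1
                agree += layer.values[r, c] == expected
        assert agree / total >= 0.99


class TestFeatureTable:
    def _toy(self):
        grid = open_grid(5)
        rng = np.random.default_rng(1)
        effort = EffortMap(grid, rng.uniform(100, 1_000, (5, 5)))
        resp = select_absences(effort, presence_cells=list(range(10)), grid=grid)
        layers = [
            PredictorLayer(f"v{i}", "continuous", rng.uniform(size=(5, 5)))
            for i in range(7)
        ] + [
            PredictorLayer(
                "habitat", "categorical", np.full((5, 5), "sand", dtype=object)
            )
        ]
        return grid, layers, resp, effort

    def test_shape_with_eight_layers(self):
        grid, layers, resp, effort = self._toy()
        table = assemble_feature_table(grid, layers, resp, effort)
        assert table.shape == (20, 11)  # 8 predictors + response + effort + cell_id
        assert list(table.columns[-3:]) == ["response", "effort_m", "cell_id"]
        assert (table.response.value_counts() == 10).all()

    def test_removing_a_layer_drops_one_column(self):
        grid, layers, resp, effort = self._toy()
        table = assemble_feature_table(grid, layers[:-1], resp, effort)
        assert table.shape[1] == 10

    def test_missing_value_raises_with_cell_listing(self):
        grid, layers, resp, effort = self._toy()
        layers[0].values[0, 0] = np.nan  # cell 0 responds
        with pytest.raises(MissingValueError, match="v0"):
            assemble_feature_table(grid, layers, resp, effort)

    def test_csv_round_trip(self, tmp_path):
        grid, layers, resp, effort = self._toy()
        table = assemble_feature_table(grid, layers, resp, effort)
        path = tmp_path / "features.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(table, back, check_exact=False, atol=1e-12)

    def test_grid_feature_frame_covers_marine_cells(self, study_area, all_layers):
        frame = grid_feature_frame(study_area.grid, all_layers)
        assert len(frame) == int(study_area.grid.marine_mask.sum())
        assert frame.notna().all().all()

    def test_misaligned_layer_rejected(self):
        grid, layers, resp, effort = self._toy()
        bad = PredictorLayer("bad", "continuous", np.zeros((3, 3)))
        with pytest.raises(ValueError, match="aligned"):
            assemble_feature_table(grid, layers + [bad], resp, effort)
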