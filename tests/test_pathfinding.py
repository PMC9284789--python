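import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtplan.costmap import CollimatorGantryMap, GantryTableMap
from dtplan.errors import PathfindingError
from dtplan.pathfinding import (
    AxisSpeedLimits,
    TrajectoryPath,
    astar_gc,
    astar_gt,
    check_deliverability,
    duplicate_paths,
    path_cost,
    project_to_feasible,
    smooth_path,
)

from conftest import brute_force_min_path_cost


def make_gt_map(cost, excluded=None, g_step=2.0, t_step=2.0):
    n_col, n_row = cost.shape
    g_ax = np.arange(n_col) * g_step
    t_half = (n_row - 1) / 2.0 * t_step
    t_ax = np.linspace(-t_half, t_half, n_row)
    gt = GantryTableMap(
        gantry_axis=g_ax,
        table_axis=t_ax,
        per_oar_layers={"o": cost},
        weights={"o": 1.0},
        combined=np.asarray(cost, float),
        exclusions=None,
    )
    if excluded is not None:
        from dtplan.collision import ExclusionGrid

        gt.exclusions = ExclusionGrid(g_ax, t_ax, np.asarray(excluded, bool), np.zeros_like(cost, bool))
    return gt


class TestAstarGt:
    def test_zero_cost_map_gives_constant_zero_path(self):
        gt = make_gt_map(np.zeros((10, 9)))
        path = astar_gt(gt)
        assert path_cost(gt, path) == 0.0
        np.testing.assert_array_equal(path, np.zeros(10))  # least travel, closest to 0

    def test_hand_map_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        cost = rng.integers(0, 16, size=(5, 5)) / 16.0
        gt = make_gt_map(cost)
        got = path_cost(gt, astar_gt(gt))
        best = min(
            sum(cost[c, rows[c]] for c in range(5))
            for rows in itertools.product(range(5), repeat=5)
            if all(abs(rows[c + 1] - rows[c]) <= 3 for c in range(4))
        )
        assert got == best

    def test_obstacle_beyond_step_limit_is_infeasible(self):
        cost = np.zeros((4, 9))
        excluded = np.zeros((4, 9), bool)
        excluded[1, :] = True  # full column blocked
        with pytest.raises(PathfindingError, match="no feasible path"):
            astar_gt(make_gt_map(cost, excluded))

    def test_detour_that_needs_too_fast_table_is_infeasible(self):
        # feasible cells in neighbouring columns separated by > 3 rows
        cost = np.zeros((3, 9))
        excluded = np.ones((3, 9), bool)
        excluded[0, 0] = excluded[2, 0] = False
        excluded[1, 8] = False  # only reachable with an 8-row jump
        with pytest.raises(PathfindingError, match="no feasible path"):
            astar_gt(make_gt_map(cost, excluded))

    def test_path_avoids_exclusions_and_respects_gradient(self):
        rng = np.random.default_rng(11)
        cost = rng.random((40, 21))
        excluded = rng.random((40, 21)) < 0.15
        excluded[:, 10] = False  # keep a feasible corridor
        gt = make_gt_map(cost, excluded)
        path = astar_gt(gt)
        rows = [gt.row_index(t) for t in path]
        assert not any(excluded[c, r] for c, r in enumerate(rows))
        assert np.all(np.abs(np.diff(path)) <= 6.0 + 1e-9)

    def test_optimal_on_random_maps_vs_dp_oracle(self, rng):
        for _ in range(25):
            cost = rng.integers(0, 16, size=(12, 11)) / 16.0
            excluded = rng.random((12, 11)) < 0.2
            excluded[:, 5] = False
            gt = make_gt_map(cost, excluded)
            expect = brute_force_min_path_cost(cost, excluded, 3)
            assert path_cost(gt, astar_gt(gt)) == expect


class TestAstarGc:
    def _gc_map(self, width, g_step=2.0):
        n_col, n_row = width.shape
        return CollimatorGantryMap(
            gantry_axis=np.arange(n_col) * g_step,
            table_angles=np.zeros(n_col),
            collimator_axis=np.arange(-180, 180, 360.0 / n_row),
            width_mm=np.asarray(width, float),
        )

    def test_constant_map_constant_at_tiebreak_angle(self):
        gc = self._gc_map(np.full((12, 36), 40.0))
        path = astar_gc(gc)
        np.testing.assert_array_equal(path, np.zeros(12))

    def test_forced_start_constant(self):
        gc = self._gc_map(np.full((12, 72), 40.0))
        path = astar_gc(gc, start_deg=95.0)
        np.testing.assert_array_equal(path, np.full(12, 95.0))

    def test_wraparound_shortest_step_allowed(self):
        # minima at -180 deg then +178 deg: 2 deg apart through the wrap
        width = np.full((2, 180), 100.0)
        width[0, 0] = 0.0    # -180 deg
        width[1, 179] = 0.0  # +178 deg
        gc = self._gc_map(width)  # gantry step 2 -> max collimator step 6 deg
        path = astar_gc(gc)
        np.testing.assert_allclose(path, [-180.0, 178.0])

    def test_tracks_rotating_footprint_vs_dp_oracle(self):
        # width map of a slowly rotating elongated footprint; collimator and
        # gantry both on 10 deg steps so up to 3 rows of motion per column
        n_col, n_row = 10, 36
        c_ax = np.arange(-180, 180, 10.0)
        width = np.empty((n_col, n_row))
        for i in range(n_col):
            phi = np.deg2rad(c_ax - 3.0 * i)
            width[i] = np.round(20.0 + 40.0 * np.abs(np.sin(phi)), 3)
        gc = self._gc_map(width, g_step=10.0)
        path = astar_gc(gc)
        rows = [int(np.argmin(np.abs(c_ax - p))) for p in path]
        got = sum(width[i, rows[i]] for i in range(n_col))
        assert got == pytest.approx(_dp_wrap_min(width, 3), abs=1e-9)
        # steps respect the circular gradient limit (3 * 10 deg)
        d = (np.diff(path) + 180.0) % 360.0 - 180.0
        assert np.all(np.abs(d) <= 30.0 + 1e-9)


def _dp_wrap_min(width, max_step):
    n_col, n_row = width.shape
    prev = list(width[0])
    for c in range(1, n_col):
        cur = [float("inf")] * n_row
        for r in range(n_row):
            best = min(prev[(r + d) % n_row] for d in range(-max_step, max_step + 1))
            cur[r] = best + width[c, r]
        prev = cur
    return min(prev)


class TestSmoothPath:
    def test_constant_unchanged(self):
        x = np.full(30, 12.5)
        np.testing.assert_array_equal(smooth_path(x, 10), x)

    def test_window_one_is_identity(self, rng):
        x = rng.random(25)
        np.testing.assert_array_equal(smooth_path(x, 1), x)

    def test_step_sequence_matches_hand_window_means(self):
        x = np.array([0.0] * 10 + [30.0] * 10)
        got = smooth_path(x, 10)
        # independent naive re-computation of the documented rule
        expect = []
        h = 5
        for i in range(20):
            k = min(h, i, 19 - i)
            expect.append(np.mean(x[i - k : i + k + 1]))
        np.testing.assert_allclose(got, expect)

    def test_contraction_on_increments(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 60))
            sm = smooth_path(x, 10)
            assert np.max(np.abs(np.diff(sm))) <= np.max(np.abs(np.diff(x))) + 1e-12

    @given(st.lists(st.floats(-90, 90), min_size=2, max_size=50), st.integers(1, 15))
    @settings(max_examples=200, deadline=None)
    def test_contraction_property(self, values, window):
        x = np.asarray(values)
        sm = smooth_path(x, window)
        assert len(sm) == len(x)
        assert np.max(np.abs(np.diff(sm))) <= np.max(np.abs(np.diff(x))) + 1e-9

    def test_projection_repairs_excluded_cells(self):
        cost = np.zeros((6, 9))
        excluded = np.zeros((6, 9), bool)
        excluded[3, 3:6] = True  # block centre rows of column 3
        gt = make_gt_map(cost, excluded)
        seq = np.zeros(6)  # lands on excluded (3, row of 0 deg)
        fixed = project_to_feasible(seq, gt)
        rows = [gt.row_index(t) for t in fixed]
        assert not any(excluded[c, r] for c, r in enumerate(rows))
        assert np.all(np.abs(np.diff(fixed)) <= 6.0 + 1e-9)


class TestDuplication:
    def _path(self, n=12):
        g = np.arange(0, 2 * n, 2.0)
        return TrajectoryPath(
            g, np.zeros(n), np.zeros(n), np.full(n, -30.0), np.full(n, 30.0), name="p"
        )

    def test_none_is_singleton(self):
        p = self._path()
        out = duplicate_paths(p, "none")
        assert len(out) == 1 and out[0] is p

    def test_split_field_partitions_with_overlap(self):
        out = duplicate_paths(self._path(), "split-field", overlap_mm=5.0)
        assert len(out) == 2
        a, b = out
        # union covers the original [-30, 30]; intersection width = overlap
        np.testing.assert_allclose(a.jaw_x1_mm, -30.0)
        np.testing.assert_allclose(a.jaw_x2_mm, 2.5)
        np.testing.assert_allclose(b.jaw_x1_mm, -2.5)
        np.testing.assert_allclose(b.jaw_x2_mm, 30.0)

    def test_collimator_offset_90_twice_returns_to_start_mod_180(self):
        p = self._path()
        once = duplicate_paths(p, "collimator-offset-90")[1]
        twice = duplicate_paths(once, "collimator-offset-90")[1]
        diff = (twice.collimator_deg - p.collimator_deg) % 180.0
        np.testing.assert_allclose(diff, 0.0)

    def test_offset_magnitude_is_90(self):
        out = duplicate_paths(self._path(), "collimator-offset-90")
        d = (out[1].collimator_deg - out[0].collimator_deg + 180.0) % 360.0 - 180.0
        np.testing.assert_allclose(np.abs(d), 90.0)


class TestDeliverability:
    def _path(self, table):
        n = len(table)
        g = np.arange(0, 2 * n, 2.0)
        z = np.zeros(n)
        return TrajectoryPath(g, np.asarray(table, float), z, z, z)

    def test_gentle_path_feasible(self):
        rep = check_deliverability(self._path(np.linspace(0, 30, 20)))
        assert rep.feasible and rep.violations == []

    def test_table_jump_reported(self):
        table = np.zeros(10)
        table[5:] = 10.0  # 10 deg over one 2 deg gantry step
        rep = check_deliverability(self._path(table), AxisSpeedLimits(table_deg_s=18.0))
        assert not rep.feasible
        assert any(idx == 5 and axis == "table" for idx, axis, *_ in rep.violations)

    def test_feasible_iff_no_violations(self, rng):
        for _ in range(10):
            table = np.cumsum(rng.uniform(-6, 6, size=15))
            rep = check_deliverability(self._path(table))
            assert rep.feasible == (len(rep.violations) == 0)


class TestValidate:
    def test_gradient_violation_detected(self):
        g = np.arange(0, 20, 2.0)
        table = np.zeros(10)
        table[5] = 10.0
        p = TrajectoryPath(g, table, np.zeros(10), np.zeros(10), np.zeros(10))
        with pytest.raises(PathfindingError, match="table gradient"):
            p.validate()

    def test_non_monotone_gantry_detected(self):
        g = np.array([0.0, 2.0, 1.0])
        z = np.zeros(3)
        with pytest.raises(PathfindingError, match="monotone"):
            TrajectoryPath(g, z, z, z, z).validate()
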