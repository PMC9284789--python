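"""A* search for minimum-cost gantry-table and collimator-gantry paths,
moving-average smoothing, duplication strategies, and deliverability checks.

The search operates on a column-ordered grid: one node per (gantry column,
row) where a row is a table or collimator angle.  A path picks exactly one
row per column; consecutive rows may differ by at most
``gradient_limit * gantry_step`` degrees, and excluded cells are impassable.
The heuristic is zero (Dijkstra-equivalent), so returned paths are provably
optimal; ties are broken deterministically by least total row travel, then by
smallest summed |angle|.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bev import BeamGeometry, StructureVolume
from .costmap import CollimatorGantryMap, GantryTableMap
from .errors import PathfindingError

__all__ = [
    "TrajectoryPath",
    "astar_gt",
    "astar_gc",
    "smooth_path",
    "smooth_path_circular",
    "project_to_feasible",
    "duplicate_paths",
    "fit_jaws",
    "check_deliverability",
    "AxisSpeedLimits",
    "DeliverabilityReport",
]


# ---------------------------------------------------------------------------
# trajectory container


@dataclass
class TrajectoryPath:
    """Ordered machine control points of one dynamic trajectory."""

    gantry_deg: np.ndarray
    table_deg: np.ndarray
    collimator_deg: np.ndarray
    jaw_x1_mm: np.ndarray
    jaw_x2_mm: np.ndarray
    name: str = "path"
    duplication: str = "none"

    def __post_init__(self) -> None:
        self.gantry_deg = np.asarray(self.gantry_deg, float)
        self.table_deg = np.asarray(self.table_deg, float)
        self.collimator_deg = np.asarray(self.collimator_deg, float)
        self.jaw_x1_mm = np.asarray(self.jaw_x1_mm, float)
        self.jaw_x2_mm = np.asarray(self.jaw_x2_mm, float)
        n = len(self.gantry_deg)
        for arr in (self.table_deg, self.collimator_deg, self.jaw_x1_mm, self.jaw_x2_mm):
            if len(arr) != n:
                raise ValueError("control point arrays must share length")

    def __len__(self) -> int:
        return len(self.gantry_deg)

    def validate(
        self,
        gantry_step_deg: float = 2.0,
        gradient_limit: float = 3.0,
        gt_map: Optional[GantryTableMap] = None,
    ) -> None:
        """Raise PathfindingError on any violated kinematic invariant."""
        dg = np.diff(self.gantry_deg)
        if not (np.all(dg > 0) or np.all(dg < 0)):
            raise PathfindingError("gantry angles must be strictly monotone")
        if not np.allclose(np.abs(dg), gantry_step_deg):
            raise PathfindingError(f"gantry spacing must be {gantry_step_deg} deg")
        max_delta = gradient_limit * gantry_step_deg + 1e-9
        if np.any(np.abs(np.diff(self.table_deg)) > max_delta):
            raise PathfindingError("table gradient limit violated")
        dcol = _circ_diff(self.collimator_deg[1:], self.collimator_deg[:-1])
        if np.any(np.abs(dcol) > max_delta):
            raise PathfindingError("collimator gradient limit violated")
        if gt_map is not None:
            for g, t in zip(self.gantry_deg, self.table_deg):
                i = gt_map.column_index(float(g) % 360.0)
                j = gt_map.row_index(float(t))
                if gt_map.excluded[i, j]:
                    raise PathfindingError(
                        f"control point (gantry {g}, table {t}) inside exclusion zone"
                    )


def _circ_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest signed angular difference a - b in degrees."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# core column-graph A*


def _astar_columns(
    cost: np.ndarray,
    excluded: np.ndarray,
    max_row_step: int,
    row_tiebreak: np.ndarray,
    row_values: np.ndarray,
    wrap_rows: bool = False,
    start_row: Optional[int] = None,
) -> Tuple[np.ndarray, float]:
    """Optimal one-row-per-column path through a (columns x rows) cost grid.

    A* with an admissible zero heuristic and lexicographic cost
    (sum of cell costs, total row travel in degrees, sum of tie-break
    magnitudes).  Returns (row indices per column, total cell cost).
    """
    n_col, n_row = cost.shape
    if excluded.shape != cost.shape:
        raise ValueError("cost and exclusion shapes differ")

    start_rows = [start_row] if start_row is not None else range(n_row)
    INF = (np.inf, np.inf, np.inf)
    best: Dict[Tuple[int, int], Tuple[float, float, float]] = {}
    parent: Dict[Tuple[int, int], Tuple[int, int]] = {}
    heap: List[Tuple[float, float, float, int, int]] = []
    for r in start_rows:
        if excluded[0, r]:
            continue
        key = (cost[0, r], 0.0, row_tiebreak[r])
        best[(0, r)] = key
        heapq.heappush(heap, (*key, 0, r))

    goal: Optional[Tuple[int, int]] = None
    while heap:
        c, trav, tb, col, row = heapq.heappop(heap)
        if best.get((col, row), INF) < (c, trav, tb):
            continue
        if col == n_col - 1:
            goal = (col, row)
            break
        ncol = col + 1
        for dr in range(-max_row_step, max_row_step + 1):
            nrow = row + dr
            if wrap_rows:
                nrow %= n_row
            elif nrow < 0 or nrow >= n_row:
                continue
            if excluded[ncol, nrow]:
                continue
            step_deg = abs(_circ_diff(row_values[nrow], row_values[row])) if wrap_rows else abs(
                row_values[nrow] - row_values[row]
            )
            cand = (c + cost[ncol, nrow], trav + float(step_deg), tb + row_tiebreak[nrow])
            if cand < best.get((ncol, nrow), INF):
                best[(ncol, nrow)] = cand
                parent[(ncol, nrow)] = (col, row)
                heapq.heappush(heap, (*cand, ncol, nrow))

    if goal is None:
        raise PathfindingError("no feasible path through the cost map")

    rows = np.empty(n_col, dtype=int)
    node = goal
    while True:
        rows[node[0]] = node[1]
        if node[0] == 0:
            break
        node = parent[node]
    return rows, float(best[goal][0])


def astar_gt(
    gt_map: GantryTableMap, gradient_limit_deg_per_deg: float = 3.0
) -> np.ndarray:
    """Minimum-cost table-angle sequence (one per gantry column).

    Start and end table angles are free; excluded cells are impassable; the
    per-column table change is limited to ``gradient_limit * gantry_step``.
    """
    g_step = float(np.median(np.abs(np.diff(gt_map.gantry_axis))))
    t_step = float(np.median(np.abs(np.diff(gt_map.table_axis))))
    max_row_step = int(np.floor(gradient_limit_deg_per_deg * g_step / t_step + 1e-9))
    rows, _ = _astar_columns(
        gt_map.combined,
        gt_map.excluded,
        max_row_step,
        row_tiebreak=np.abs(gt_map.table_axis),
        row_values=gt_map.table_axis,
        wrap_rows=False,
    )
    return gt_map.table_axis[rows]


def path_cost(gt_map: GantryTableMap, table_sequence: Sequence[float]) -> float:
    """Sum of combined-map cell costs along a table-angle sequence."""
    total = 0.0
    for g, t in zip(gt_map.gantry_axis, table_sequence):
        i = gt_map.column_index(float(g))
        j = gt_map.row_index(float(t))
        if gt_map.excluded[i, j]:
            return float("inf")
        total += float(gt_map.combined[i, j])
    return total


def astar_gc(
    gc_map: CollimatorGantryMap,
    gradient_limit_deg_per_deg: float = 3.0,
    start_deg: Optional[float] = None,
) -> np.ndarray:
    """Minimum-width collimator-angle sequence along the GT path.

    The collimator axis is circular (wraps at +-180 deg); the field-width
    cost is 180 deg-periodic by construction.
    """
    g_step = float(np.median(np.abs(np.diff(gc_map.gantry_axis))))
    c_step = float(np.median(np.abs(np.diff(gc_map.collimator_axis))))
    max_row_step = int(np.floor(gradient_limit_deg_per_deg * g_step / c_step + 1e-9))
    start_row = None
    if start_deg is not None:
        start_row = int(np.argmin(np.abs(_circ_diff(gc_map.collimator_axis, start_deg))))
    rows, _ = _astar_columns(
        gc_map.width_mm,
        np.zeros_like(gc_map.width_mm, dtype=bool),
        max_row_step,
        row_tiebreak=np.abs(gc_map.collimator_axis),
        row_values=gc_map.collimator_axis,
        wrap_rows=True,
        start_row=start_row,
    )
    return gc_map.collimator_axis[rows]


# ---------------------------------------------------------------------------
# smoothing


def smooth_path(values: Sequence[float], window_points: int = 10) -> np.ndarray:
    """Centred moving average with windows shrinking symmetrically at the
    ends; output length equals input length.

    Even window sizes are widened to the next odd size so the window can be
    centred (the default 10 becomes 11 points, spanning 20 deg of gantry at
    2 deg control-point spacing).  A symmetric centred average never increases
    the maximum absolute per-step increment.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty sequence")
    if window_points < 1:
        raise ValueError("window must be >= 1")
    h = window_points // 2
    out = np.empty(n)
    for i in range(n):
        k = min(h, i, n - 1 - i)
        out[i] = x[i] if k == 0 else x[i - k : i + k + 1].mean()
    return out


def smooth_path_circular(values: Sequence[float], window_points: int = 10) -> np.ndarray:
    """Moving average for a circular axis (e.g. collimator): the sequence is
    unwrapped before averaging and wrapped back to [-180, 180)."""
    x = np.asarray(values, dtype=float)
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(x)))
    out = smooth_path(unwrapped, window_points)
    return (out + 180.0) % 360.0 - 180.0


def project_to_feasible(
    table_sequence: Sequence[float],
    gt_map: GantryTableMap,
    gradient_limit_deg_per_deg: float = 3.0,
) -> np.ndarray:
    """Push any control point that landed in an exclusion cell (e.g. after
    smoothing) to the nearest feasible table angle in its column, then clamp
    against both neighbours and re-validate the gradient limit."""
    seq = np.asarray(table_sequence, float).copy()
    g_step = float(np.median(np.abs(np.diff(gt_map.gantry_axis))))
    max_delta = gradient_limit_deg_per_deg * g_step
    for i, g in enumerate(gt_map.gantry_axis):
        col = gt_map.column_index(float(g))
        row = gt_map.row_index(seq[i])
        if not gt_map.excluded[col, row]:
            continue
        feasible = np.flatnonzero(~gt_map.excluded[col])
        if feasible.size == 0:
            raise PathfindingError("no feasible path: fully excluded gantry column")
        j = feasible[np.argmin(np.abs(gt_map.table_axis[feasible] - seq[i]))]
        seq[i] = gt_map.table_axis[j]
    # clamp forward and backward so projection cannot break the gradient
    for i in range(1, len(seq)):
        seq[i] = np.clip(seq[i], seq[i - 1] - max_delta, seq[i - 1] + max_delta)
    for i in range(len(seq) - 2, -1, -1):
        seq[i] = np.clip(seq[i], seq[i + 1] - max_delta, seq[i + 1] + max_delta)
    if not _violates_exclusion(seq, gt_map):
        return seq
    # clamping re-entered an exclusion cell: fall back to the feasible
    # on-grid sequence closest (L1) to the smoothed one, found with the same
    # optimal search on a deviation cost map
    deviation = np.abs(gt_map.table_axis[None, :] - np.asarray(table_sequence, float)[:, None])
    g_cols = np.array([gt_map.column_index(float(g)) for g in gt_map.gantry_axis])
    t_step = float(np.median(np.abs(np.diff(gt_map.table_axis))))
    max_row_step = int(np.floor(max_delta / t_step + 1e-9))
    rows, _ = _astar_columns(
        deviation,
        gt_map.excluded[g_cols],
        max_row_step,
        row_tiebreak=np.abs(gt_map.table_axis),
        row_values=gt_map.table_axis,
        wrap_rows=False,
    )
    return gt_map.table_axis[rows]


def _violates_exclusion(seq: np.ndarray, gt_map: GantryTableMap) -> bool:
    for i, g in enumerate(gt_map.gantry_axis):
        col = gt_map.column_index(float(g))
        if gt_map.excluded[col, gt_map.row_index(seq[i])]:
            return True
    return False


# ---------------------------------------------------------------------------
# jaws and duplication


def fit_jaws(
    path: TrajectoryPath,
    target: StructureVolume,
    sad_mm: float = 1000.0,
    margin_mm: float = 5.0,
) -> TrajectoryPath:
    """Set x-jaws per control point to the target BEV extent in the rotated
    leaf-travel direction, plus a field margin."""
    x1 = np.empty(len(path))
    x2 = np.empty(len(path))
    for i in range(len(path)):
        geom = BeamGeometry(
            gantry_deg=float(path.gantry_deg[i]) % 360.0,
            table_deg=float(path.table_deg[i]),
            sad_mm=sad_mm,
        )
        lo, hi = _footprint_x_extent(target, geom, float(path.collimator_deg[i]))
        x1[i] = lo - margin_mm
        x2[i] = hi + margin_mm
    return replace(path, jaw_x1_mm=x1, jaw_x2_mm=x2)


def _footprint_x_extent(
    target: StructureVolume, geometry: BeamGeometry, collimator_deg: float
) -> Tuple[float, float]:
    from .bev import _project_points, beam_frame

    source, d, xb, yb = beam_frame(geometry)
    xy, _ = _project_points(target.points_mm(), source, d, xb, yb, geometry.sad_mm)
    c = np.deg2rad(collimator_deg)
    proj = xy[:, 0] * np.cos(c) + xy[:, 1] * np.sin(c)
    return float(proj.min()), float(proj.max())


def duplicate_paths(
    path: TrajectoryPath,
    strategy: str,
    target: Optional[StructureVolume] = None,
    overlap_mm: float = 5.0,
    sad_mm: float = 1000.0,
) -> List[TrajectoryPath]:
    """Expand one optimised path into its delivered set.

    ``split-field``: two copies whose x-jaws partition the target BEV
    x-extent at its midpoint with ``overlap_mm`` of shared field.
    ``collimator-offset-90``: second copy with the collimator offset by a
    constant 90 deg (wrapped) and jaws re-fit.  ``none``: singleton.
    """
    if strategy == "none":
        return [path]
    if strategy == "split-field":
        a = replace(path, name=f"{path.name}-a", duplication="split-field")
        b = replace(path, name=f"{path.name}-b", duplication="split-field")
        mid = (path.jaw_x1_mm + path.jaw_x2_mm) / 2.0
        a.jaw_x2_mm = mid + overlap_mm / 2.0
        b.jaw_x1_mm = mid - overlap_mm / 2.0
        return [a, b]
    if strategy == "collimator-offset-90":
        col2 = (path.collimator_deg + 90.0 + 180.0) % 360.0 - 180.0
        b = replace(path, collimator_deg=col2, name=f"{path.name}-crot", duplication="collimator-offset-90")
        if target is not None:
            b = fit_jaws(b, target, sad_mm=sad_mm)
        return [replace(path, duplication="collimator-offset-90"), b]
    raise ValueError(f"unknown duplication strategy {strategy!r}")


# ---------------------------------------------------------------------------
# deliverability


@dataclass(frozen=True)
class AxisSpeedLimits:
    """Maximum axis speeds (deg/s or mm/s) with gantry at full speed."""

    gantry_deg_s: float = 6.0
    table_deg_s: float = 18.0
    collimator_deg_s: float = 18.0
    jaw_mm_s: float = 50.0


@dataclass
class DeliverabilityReport:
    feasible: bool
    violations: List[Tuple[int, str, float, float]] = field(default_factory=list)
    # (control point index, axis, required speed, limit)


def check_deliverability(
    path: TrajectoryPath, limits: AxisSpeedLimits = AxisSpeedLimits()
) -> DeliverabilityReport:
    """Flag inter-point motion exceeding axis speed limits when the gantry
    rotates at its maximum speed."""
    dg = np.abs(np.diff(path.gantry_deg))
    if np.any(dg <= 0):
        raise ValueError("gantry must be strictly monotone")
    dt = dg / limits.gantry_deg_s
    checks = {
        "table": (np.abs(np.diff(path.table_deg)), limits.table_deg_s),
        "collimator": (np.abs(_circ_diff(path.collimator_deg[1:], path.collimator_deg[:-1])), limits.collimator_deg_s),
        "jaw_x1": (np.abs(np.diff(path.jaw_x1_mm)), limits.jaw_mm_s),
        "jaw_x2": (np.abs(np.diff(path.jaw_x2_mm)), limits.jaw_mm_s),
    }
    violations: List[Tuple[int, str, float, float]] = []
    for axis, (delta, limit) in checks.items():
        speed = delta / dt
        for idx in np.flatnonzero(speed > limit + 1e-9):
            violations.append((int(idx + 1), axis, float(speed[idx]), float(limit)))
    return DeliverabilityReport(feasible=len(violations) == 0, violations=sorted(violations))
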