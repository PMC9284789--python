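"""End-to-end planning pipeline: structures + run config -> trajectory set.

One recipe produces one optimised gantry-table-collimator path which the
duplication strategy then expands (split-field or constant 90 deg collimator
offset), mirroring the per-path plan layout of the clinical workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

from .bev import StructureVolume
from .collision import LinacClearance, PatientTableEnvelope
from .costmap import (
    GantryTableMap,
    PathRecipe,
    build_gc_map,
    build_gt_map,
    default_collimator_axis,
    default_gantry_axis,
    default_table_axis,
    weighted_recipe_from_config,
)
from .errors import ConfigError
from .pathfinding import (
    TrajectoryPath,
    astar_gc,
    astar_gt,
    duplicate_paths,
    fit_jaws,
    project_to_feasible,
    smooth_path,
    smooth_path_circular,
)

__all__ = ["PlanSettings", "plan_recipe", "plan_case"]


@dataclass
class PlanSettings:
    """Knobs of the geometric planning stage; defaults follow the published
    protocol where one exists (2 deg control points, 3 deg/deg gradient,
    10-point smoothing window, 2 cm collision margin)."""

    gantry_step_deg: float = 2.0
    table_step_deg: float = 2.0
    collimator_step_deg: float = 2.0
    gradient_limit: float = 3.0
    smoothing_window: int = 10
    sad_mm: float = 1000.0
    depth_weights: tuple = (1.0, 0.5)
    raster_mm: float = 1.0
    jaw_margin_mm: float = 5.0
    split_overlap_mm: float = 5.0
    clearance: Optional[LinacClearance] = None
    envelope: Optional[PatientTableEnvelope] = None


def plan_recipe(
    target: StructureVolume,
    structures: Mapping[str, StructureVolume],
    recipe: PathRecipe,
    settings: PlanSettings = PlanSettings(),
    gt_map: Optional[GantryTableMap] = None,
) -> List[TrajectoryPath]:
    """Optimise one recipe into its delivered trajectory set.

    A precomputed GT map may be passed in (the map depends only on the OAR
    selection, so callers batching several recipes can reuse it).
    """
    oars, weights, strategy = weighted_recipe_from_config(recipe, structures)
    if gt_map is None:
        gt_map = build_gt_map(
            target,
            oars,
            weights=weights,
            gantry_axis=default_gantry_axis(settings.gantry_step_deg),
            table_axis=default_table_axis(settings.table_step_deg),
            sad_mm=settings.sad_mm,
            depth_weights=settings.depth_weights,
            raster_mm=settings.raster_mm,
            clearance=settings.clearance,
            envelope=settings.envelope,
        )
    table = astar_gt(gt_map, settings.gradient_limit)
    table = smooth_path(table, settings.smoothing_window)
    table = project_to_feasible(table, gt_map, settings.gradient_limit)

    gc_map = build_gc_map(
        target,
        gt_map.gantry_axis,
        table,
        collimator_axis=default_collimator_axis(settings.collimator_step_deg),
        sad_mm=settings.sad_mm,
    )
    collimator = astar_gc(gc_map, settings.gradient_limit)
    collimator = smooth_path_circular(collimator, settings.smoothing_window)

    path = TrajectoryPath(
        gantry_deg=gt_map.gantry_axis.copy(),
        table_deg=np.asarray(table, float),
        collimator_deg=np.asarray(collimator, float),
        jaw_x1_mm=np.zeros(len(gt_map.gantry_axis)),
        jaw_x2_mm=np.zeros(len(gt_map.gantry_axis)),
        name=recipe.name,
    )
    path = fit_jaws(path, target, sad_mm=settings.sad_mm, margin_mm=settings.jaw_margin_mm)
    return duplicate_paths(
        path, strategy, target=target, overlap_mm=settings.split_overlap_mm, sad_mm=settings.sad_mm
    )


def plan_case(
    structures: Mapping[str, StructureVolume],
    recipes: List[PathRecipe],
    settings: PlanSettings = PlanSettings(),
) -> List[TrajectoryPath]:
    """Plan all recipes of a case; returns the flat list of trajectories."""
    targets = [s for s in structures.values() if s.role == "target"]
    if len(targets) != 1:
        raise ConfigError(f"expected exactly one target structure, found {len(targets)}")
    out: List[TrajectoryPath] = []
    for recipe in recipes:
        out.extend(plan_recipe(targets[0], structures, recipe, settings))
    return out
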