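"""Gantry-table (GT) overlap cost maps and collimator-gantry (GC)
field-width maps.

A GT map holds one overlap layer per OAR over a grid of (gantry, table)
angles — by default 2 deg steps over [0, 360) x [-90, +90] — combined as a
weight-normalised sum so the combined cost stays in [0, 1].  Excluded cells
(collision or CT-length) are flagged separately and treated as infinite cost
by the path-finder.

A GC map quantifies, along a chosen GT path, the target's BEV extent in the
leaf-travel (x) direction as a function of collimator angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .bev import (
    BeamGeometry,
    BevProjection,
    StructureVolume,
    _FootprintRaster,
    _overlap_from_projections,
    _project_points,
    beam_frame,
)
from .collision import ExclusionGrid, LinacClearance, PatientTableEnvelope, exclusion_mask
from .errors import ConfigError, EmptyStructureError

__all__ = [
    "GantryTableMap",
    "CollimatorGantryMap",
    "PathRecipe",
    "build_gt_map",
    "build_gc_map",
    "weighted_recipe_from_config",
    "default_gantry_axis",
    "default_table_axis",
    "default_collimator_axis",
]

DUPLICATION_STRATEGIES = ("none", "split-field", "collimator-offset-90")


def default_gantry_axis(step_deg: float = 2.0) -> np.ndarray:
    """Full rotation, half-open: [0, 360)."""
    return np.arange(0.0, 360.0, step_deg)


def default_table_axis(step_deg: float = 2.0) -> np.ndarray:
    return np.arange(-90.0, 90.0 + 0.5 * step_deg, step_deg)


def default_collimator_axis(step_deg: float = 2.0) -> np.ndarray:
    return np.arange(-180.0, 180.0, step_deg)


@dataclass
class GantryTableMap:
    gantry_axis: np.ndarray
    table_axis: np.ndarray
    per_oar_layers: Dict[str, np.ndarray]
    weights: Dict[str, float]
    combined: np.ndarray
    exclusions: Optional[ExclusionGrid] = None

    @property
    def excluded(self) -> np.ndarray:
        if self.exclusions is None:
            return np.zeros(self.combined.shape, dtype=bool)
        return self.exclusions.combined

    def column_index(self, gantry_deg: float) -> int:
        return int(np.argmin(np.abs(self.gantry_axis - gantry_deg)))

    def row_index(self, table_deg: float) -> int:
        return int(np.argmin(np.abs(self.table_axis - table_deg)))


@dataclass
class CollimatorGantryMap:
    gantry_axis: np.ndarray           # along the GT path
    table_angles: np.ndarray          # table angle at each gantry column
    collimator_axis: np.ndarray
    width_mm: np.ndarray              # (n_gantry, n_collimator)


@dataclass
class PathRecipe:
    """One path of a plan: which OARs drive the GT map, how it is duplicated."""

    name: str
    oar_names: Sequence[str]
    strategy: str = "none"
    weights: Optional[Mapping[str, float]] = None


def combine_layers(
    layers: Mapping[str, np.ndarray], weights: Mapping[str, float]
) -> np.ndarray:
    """Weighted sum normalised by the total weight (stays in [0, 1])."""
    total_w = sum(weights[k] for k in layers)
    if total_w <= 0:
        raise ConfigError("empty OAR selection: total weight is zero")
    out = np.zeros_like(next(iter(layers.values())))
    for k, layer in layers.items():
        out = out + weights[k] * layer
    return out / total_w


def build_gt_map(
    target: StructureVolume,
    oars: Sequence[StructureVolume],
    weights: Optional[Mapping[str, float]] = None,
    gantry_axis: Optional[np.ndarray] = None,
    table_axis: Optional[np.ndarray] = None,
    sad_mm: float = 1000.0,
    depth_weights: Tuple[float, float] = (1.0, 0.5),
    raster_mm: float = 1.0,
    clearance: Optional[LinacClearance] = None,
    envelope: Optional[PatientTableEnvelope] = None,
) -> GantryTableMap:
    """Assemble per-OAR overlap layers and the combined GT cost map.

    The target projection and footprint raster are computed once per
    (gantry, table) cell and shared across all OAR layers.
    """
    if len(oars) == 0:
        raise ConfigError("empty OAR selection")
    if gantry_axis is None:
        gantry_axis = default_gantry_axis()
    if table_axis is None:
        table_axis = default_table_axis()
    if weights is None:
        weights = {o.name: 1.0 for o in oars}

    excl: Optional[ExclusionGrid] = None
    if clearance is not None and envelope is not None:
        excl = exclusion_mask(gantry_axis, table_axis, clearance, envelope, target)
    excluded = (
        excl.combined if excl is not None else np.zeros((len(gantry_axis), len(table_axis)), bool)
    )

    tgt_pts = target.points_mm()
    oar_pts = {o.name: o.points_mm() for o in oars}
    voxel_extent = float(target.spacing_mm.max())
    layers = {o.name: np.zeros((len(gantry_axis), len(table_axis))) for o in oars}

    for i, g in enumerate(gantry_axis):
        for j, t in enumerate(table_axis):
            if excluded[i, j]:
                continue
            geom = BeamGeometry(gantry_deg=float(g), table_deg=float(t), sad_mm=sad_mm)
            source, d, xb, yb = beam_frame(geom)
            t_xy, t_depth = _project_points(tgt_pts, source, d, xb, yb, sad_mm)
            mag = float(sad_mm / np.median(t_depth))
            raster = _FootprintRaster(t_xy, voxel_extent, mag, raster_mm)
            t_med = float(np.median(t_depth))
            for o in oars:
                o_xy, o_depth = _project_points(oar_pts[o.name], source, d, xb, yb, sad_mm)
                layers[o.name][i, j] = _overlap_from_projections(
                    raster,
                    t_med,
                    BevProjection(o_xy, o_depth, sad_mm),
                    depth_weights[0],
                    depth_weights[1],
                )

    combined = combine_layers(layers, dict(weights))
    return GantryTableMap(
        gantry_axis=np.asarray(gantry_axis, float),
        table_axis=np.asarray(table_axis, float),
        per_oar_layers=layers,
        weights=dict(weights),
        combined=combined,
        exclusions=excl,
    )


def bev_footprint_width(
    target: StructureVolume,
    geometry: BeamGeometry,
    collimator_deg: np.ndarray,
) -> np.ndarray:
    """Extent of the target BEV footprint along the leaf-travel (x) direction
    after rotating the footprint by -collimator about the beam axis.

    Vectorised over collimator angles; widths are measured between projected
    voxel centres.  Periodic in the collimator angle with period 180 deg.
    """
    if not target.mask.any():
        raise EmptyStructureError(f"empty structure: {target.name!r}")
    source, d, xb, yb = beam_frame(geometry)
    xy, _ = _project_points(target.points_mm(), source, d, xb, yb, geometry.sad_mm)
    c = np.deg2rad(np.asarray(collimator_deg, float))
    # x-coordinate in the collimator-rotated frame
    proj = xy[:, 0][:, None] * np.cos(c)[None, :] + xy[:, 1][:, None] * np.sin(c)[None, :]
    return proj.max(axis=0) - proj.min(axis=0)


def build_gc_map(
    target: StructureVolume,
    gantry_angles: Sequence[float],
    table_angles: Sequence[float],
    collimator_axis: Optional[np.ndarray] = None,
    sad_mm: float = 1000.0,
) -> CollimatorGantryMap:
    """Field-width map along a GT path: one row per gantry control point."""
    if collimator_axis is None:
        collimator_axis = default_collimator_axis()
    gantry_angles = np.asarray(gantry_angles, float)
    table_angles = np.asarray(table_angles, float)
    if gantry_angles.shape != table_angles.shape:
        raise ValueError("gantry and table angle sequences must align")
    width = np.zeros((len(gantry_angles), len(collimator_axis)))
    for i, (g, t) in enumerate(zip(gantry_angles, table_angles)):
        geom = BeamGeometry(gantry_deg=float(g), table_deg=float(t), sad_mm=sad_mm)
        width[i] = bev_footprint_width(target, geom, collimator_axis)
    return CollimatorGantryMap(
        gantry_axis=gantry_angles,
        table_angles=table_angles,
        collimator_axis=np.asarray(collimator_axis, float),
        width_mm=width,
    )


def weighted_recipe_from_config(
    recipe: PathRecipe, structures: Mapping[str, StructureVolume]
) -> Tuple[List[StructureVolume], Dict[str, float], str]:
    """Resolve a path recipe against available structures.

    Returns (OAR structures, weights, duplication strategy); OARs are equally
    weighted unless the recipe overrides.
    """
    if len(recipe.oar_names) == 0:
        raise ConfigError(f"empty OAR selection in recipe {recipe.name!r}")
    if recipe.strategy not in DUPLICATION_STRATEGIES:
        raise ConfigError(
            f"unknown duplication strategy {recipe.strategy!r}; expected one of {DUPLICATION_STRATEGIES}"
        )
    oars = []
    for name in recipe.oar_names:
        if name not in structures:
            raise ConfigError(f"unknown structure: {name!r}")
        oars.append(structures[name])
    if recipe.weights is not None:
        weights = {n: float(recipe.weights[n]) for n in recipe.oar_names}
    else:
        weights = {n: 1.0 for n in recipe.oar_names}
    return oars, weights, recipe.strategy
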