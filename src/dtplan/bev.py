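"""Beam's-eye-view (BEV) geometry: structure volumes, beam frames, divergent
projection, and the fractional target/OAR overlap that drives gantry-table
cost maps.

Coordinate conventions (used everywhere in the package)
-------------------------------------------------------
Patient frame (= table frame; the voxel grid lives here, mm, isocenter at the
origin):

* ``x`` — lateral (towards patient left),
* ``y`` — vertical (towards anterior / up for a supine patient),
* ``z`` — longitudinal (towards superior).

Room frame: identical to the patient frame at table angle 0.  The gantry
rotates about the room ``z`` axis; the source sits at
``sad * (sin g, cos g, 0)`` for gantry angle ``g`` (source above the patient
at ``g = 0``, IEC-61217-like).  The table rotates the *patient* about the
vertical room ``y`` axis by the table angle ``t``:
``p_room = R_y(t) @ p_patient``.

All angles are degrees; gantry in ``[0, 360)``, table in ``[-90, +90]``,
collimator in ``[-180, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .errors import EmptyStructureError

__all__ = [
    "StructureVolume",
    "BeamGeometry",
    "BevProjection",
    "beam_direction",
    "beam_frame",
    "project_to_bev",
    "overlap_fraction",
]


@dataclass
class StructureVolume:
    """Named binary mask on a regular 3D grid.

    ``mask`` is indexed ``[ix, iy, iz]`` matching the (x, y, z) patient axes.
    ``origin_mm`` is the patient-frame coordinate of the centre of voxel
    ``(0, 0, 0)``; ``isocenter_mm`` is expressed in the same frame.
    """

    name: str
    role: str  # "target" | "oar" | "body"
    mask: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    isocenter_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.isocenter_mm is None:
            self.isocenter_mm = np.zeros(3)
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-dimensional")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be positive")
        if self.role == "target" and not self.mask.any():
            raise EmptyStructureError(f"empty structure: target {self.name!r}")
        self._points_cache: np.ndarray | None = None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def points_mm(self) -> np.ndarray:
        """(N, 3) voxel-centre coordinates relative to the isocenter."""
        if self._points_cache is None:
            idx = np.argwhere(self.mask)
            if idx.size == 0:
                raise EmptyStructureError(f"empty structure: {self.name!r}")
            self._points_cache = (
                idx * self.spacing_mm + self.origin_mm - self.isocenter_mm
            )
        return self._points_cache


@dataclass(frozen=True)
class BeamGeometry:
    """One gantry/table combination for a fixed source-axis distance."""

    gantry_deg: float
    table_deg: float = 0.0
    sad_mm: float = 1000.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.table_deg <= 90.0:
            raise ValueError(f"table angle {self.table_deg} outside [-90, 90]")
        if self.sad_mm <= 0:
            raise ValueError("sad_mm must be positive")
        object.__setattr__(self, "gantry_deg", float(self.gantry_deg) % 360.0)


@dataclass
class BevProjection:
    """Projected voxel centres of one structure on the isocenter plane.

    ``xy_mm``: (N, 2) coordinates in the collimator-unrotated BEV frame
    (x = cross-plane / leaf-travel direction at collimator 0, y = longitudinal).
    ``depth_mm``: signed distance of each voxel from the source along the beam
    axis (isocenter sits at ``sad_mm``).
    """

    xy_mm: np.ndarray
    depth_mm: np.ndarray
    sad_mm: float


def _rot_y(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def beam_direction(geometry: BeamGeometry) -> np.ndarray:
    """Unit source-to-isocenter vector in the patient frame."""
    return beam_frame(geometry)[1]


def beam_frame(geometry: BeamGeometry) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Source position and orthonormal beam basis in the patient frame.

    Returns ``(source, d, x_b, y_b)`` where ``d`` is the beam axis
    (source -> isocenter), ``x_b`` the BEV x axis (leaf travel at collimator
    0) and ``y_b`` the BEV y axis; ``(x_b, y_b, d)`` is right-handed.
    """
    g = np.deg2rad(geometry.gantry_deg)
    d_room = np.array([-np.sin(g), -np.cos(g), 0.0])
    xb_room = np.array([np.cos(g), -np.sin(g), 0.0])
    yb_room = np.array([0.0, 0.0, 1.0])
    # patient -> room is R_y(t); room vectors map back with R_y(-t)
    rt = _rot_y(-geometry.table_deg)
    d = rt @ d_room
    xb = rt @ xb_room
    yb = rt @ yb_room
    source = -geometry.sad_mm * d
    return source, d, xb, yb


def _project_points(
    points: np.ndarray, source: np.ndarray, d: np.ndarray, xb: np.ndarray, yb: np.ndarray, sad: float
) -> Tuple[np.ndarray, np.ndarray]:
    v = points - source
    depth = v @ d
    if np.any(depth <= 0):
        raise ValueError("structure extends behind the source")
    scale = (sad / depth)[:, None]
    on_plane = source + v * scale
    xy = np.stack([on_plane @ xb, on_plane @ yb], axis=1)
    return xy, depth


def project_to_bev(structure: StructureVolume, geometry: BeamGeometry) -> BevProjection:
    """Divergent (point-source) projection of voxel centres onto the
    isocenter plane perpendicular to the beam axis."""
    source, d, xb, yb = beam_frame(geometry)
    xy, depth = _project_points(structure.points_mm(), source, d, xb, yb, geometry.sad_mm)
    return BevProjection(xy_mm=xy, depth_mm=depth, sad_mm=geometry.sad_mm)


class _FootprintRaster:
    """Boolean occupancy raster of a projected target footprint.

    Each projected voxel centre paints a square of half-width ~ its magnified
    voxel footprint, so the raster approximates the true silhouette to within
    about one raster cell.
    """

    def __init__(self, xy: np.ndarray, voxel_extent_mm: float, magnification: float, raster_mm: float = 1.0):
        self.raster_mm = float(raster_mm)
        half = 0.5 * voxel_extent_mm * magnification
        self.pad_cells = max(1, int(round(half / self.raster_mm)))
        self.x0 = xy[:, 0].min() - (self.pad_cells + 1) * self.raster_mm
        self.y0 = xy[:, 1].min() - (self.pad_cells + 1) * self.raster_mm
        nx = int(np.ceil((xy[:, 0].max() - self.x0) / self.raster_mm)) + self.pad_cells + 2
        ny = int(np.ceil((xy[:, 1].max() - self.y0) / self.raster_mm)) + self.pad_cells + 2
        self.grid = np.zeros((nx, ny), dtype=bool)
        ix = ((xy[:, 0] - self.x0) / self.raster_mm).astype(int)
        iy = ((xy[:, 1] - self.y0) / self.raster_mm).astype(int)
        k = self.pad_cells
        for dx in range(-k, k + 1):
            for dy in range(-k, k + 1):
                self.grid[ix + dx, iy + dy] = True

    def contains(self, xy: np.ndarray) -> np.ndarray:
        ix = np.floor((xy[:, 0] - self.x0) / self.raster_mm).astype(int)
        iy = np.floor((xy[:, 1] - self.y0) / self.raster_mm).astype(int)
        ok = (ix >= 0) & (ix < self.grid.shape[0]) & (iy >= 0) & (iy < self.grid.shape[1])
        out = np.zeros(len(xy), dtype=bool)
        out[ok] = self.grid[ix[ok], iy[ok]]
        return out


def _target_raster(target_proj: BevProjection, voxel_extent_mm: float, raster_mm: float = 1.0) -> _FootprintRaster:
    mag = float(target_proj.sad_mm / np.median(target_proj.depth_mm))
    return _FootprintRaster(target_proj.xy_mm, voxel_extent_mm, mag, raster_mm)


def _overlap_from_projections(
    raster: _FootprintRaster,
    target_median_depth: float,
    oar_proj: BevProjection,
    weight_upstream: float,
    weight_downstream: float,
) -> float:
    inside = raster.contains(oar_proj.xy_mm)
    w = np.where(oar_proj.depth_mm < target_median_depth, weight_upstream, weight_downstream)
    w_max = max(weight_upstream, weight_downstream)
    if w_max <= 0:
        return 0.0
    return float((w * inside).sum() / (len(w) * w_max))


def overlap_fraction(
    target: StructureVolume,
    oar: StructureVolume,
    geometry: BeamGeometry,
    weights: Tuple[float, float] = (1.0, 1.0),
    raster_mm: float = 1.0,
) -> float:
    """Fraction of OAR voxels whose BEV projection lands inside the target's
    BEV footprint, depth-weighted by position relative to the target.

    ``weights = (upstream, downstream)``: an OAR voxel closer to the source
    than the target's median depth counts with the upstream weight, otherwise
    with the downstream weight.  The sum is normalised by
    ``n_oar * max(weights)`` so the result lies in [0, 1]; with both weights
    equal to 1 this is the plain fractional geometric overlap.
    """
    if not target.mask.any():
        raise EmptyStructureError(f"empty structure: {target.name!r}")
    if not oar.mask.any():
        raise EmptyStructureError(f"empty structure: {oar.name!r}")
    tp = project_to_bev(target, geometry)
    op = project_to_bev(oar, geometry)
    raster = _target_raster(tp, float(target.spacing_mm.max()), raster_mm)
    return _overlap_from_projections(
        raster, float(np.median(tp.depth_mm)), op, weights[0], weights[1]
    )
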