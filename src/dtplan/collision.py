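"""Analytic gantry/table collision and CT-length exclusion model.

The linac head is modelled as the part of a ring around the room longitudinal
axis: surface at ``gantry_clearance_radius_mm`` from the rotation axis,
longitudinal half-extent ``gantry_slab_halfwidth_mm``, occupying an azimuthal
sector of half-angle ``head_halfangle_deg`` centred on the current gantry
angle.  The patient + table top are an axis-aligned box in the table frame,
sampled on its edges.  A safety margin is applied to *each* component
(envelope and gantry), i.e. the effective clearance shrinks by twice the
margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .bev import BeamGeometry, StructureVolume, _rot_y, beam_frame

__all__ = [
    "LinacClearance",
    "PatientTableEnvelope",
    "collides",
    "ct_length_exclusion",
    "ExclusionGrid",
    "exclusion_mask",
]


@dataclass(frozen=True)
class LinacClearance:
    gantry_clearance_radius_mm: float = 400.0
    gantry_slab_halfwidth_mm: float = 300.0
    safety_margin_mm: float = 20.0
    head_halfangle_deg: float = 30.0
    sad_mm: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "gantry_clearance_radius_mm",
            "gantry_slab_halfwidth_mm",
            "head_halfangle_deg",
            "sad_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.safety_margin_mm < 0:
            raise ValueError("safety_margin_mm must be non-negative")


@dataclass
class PatientTableEnvelope:
    """Bounding box of patient + table top, in the table (= patient) frame."""

    box_min_mm: np.ndarray
    box_max_mm: np.ndarray
    headrest_ref_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    ct_extent_mm: tuple[float, float] = (-1e9, 1e9)
    edge_sample_mm: float = 10.0

    def __post_init__(self) -> None:
        self.box_min_mm = np.asarray(self.box_min_mm, dtype=float)
        self.box_max_mm = np.asarray(self.box_max_mm, dtype=float)
        if self.headrest_ref_mm is None:
            self.headrest_ref_mm = np.array([0.0, 0.0, self.box_max_mm[2]])
        self.headrest_ref_mm = np.asarray(self.headrest_ref_mm, dtype=float)
        if np.any(self.box_max_mm <= self.box_min_mm):
            raise ValueError("envelope box is degenerate")
        if self.ct_extent_mm[1] <= self.ct_extent_mm[0]:
            raise ValueError("ct_extent_mm is degenerate")
        self._edge_points: np.ndarray | None = None

    def edge_points(self) -> np.ndarray:
        """Sample points on the 12 box edges (includes the 8 corners)."""
        if self._edge_points is None:
            lo, hi = self.box_min_mm, self.box_max_mm
            pts = []
            for axis in range(3):
                n = max(2, int(np.ceil((hi[axis] - lo[axis]) / self.edge_sample_mm)) + 1)
                line = np.linspace(lo[axis], hi[axis], n)
                others = [a for a in range(3) if a != axis]
                for va in (lo[others[0]], hi[others[0]]):
                    for vb in (lo[others[1]], hi[others[1]]):
                        seg = np.empty((n, 3))
                        seg[:, axis] = line
                        seg[:, others[0]] = va
                        seg[:, others[1]] = vb
                        pts.append(seg)
            self._edge_points = np.unique(np.vstack(pts), axis=0)
        return self._edge_points


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def collides(
    geometry: BeamGeometry,
    clearance: LinacClearance,
    envelope: PatientTableEnvelope,
) -> bool:
    """True iff the table-rotated envelope reaches into the gantry head's
    swept sector for this gantry angle, margins applied on each component."""
    pts = envelope.edge_points() @ _rot_y(geometry.table_deg).T  # table -> room
    m2 = 2.0 * clearance.safety_margin_mm
    radial = np.hypot(pts[:, 0], pts[:, 1])
    in_slab = np.abs(pts[:, 2]) <= clearance.gantry_slab_halfwidth_mm + m2
    too_far_out = radial >= clearance.gantry_clearance_radius_mm - m2
    cand = in_slab & too_far_out
    if not cand.any():
        return False
    azimuth = np.rad2deg(np.arctan2(pts[cand, 0], pts[cand, 1]))
    dz = np.abs(_wrap_deg(azimuth - geometry.gantry_deg))
    return bool(np.any(dz <= clearance.head_halfangle_deg))


def _target_corners(target: StructureVolume, margin_mm: float = 5.0) -> np.ndarray:
    pts = target.points_mm()
    lo = pts.min(axis=0) - margin_mm
    hi = pts.max(axis=0) + margin_mm
    return np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])


def ct_length_exclusion(
    geometry: BeamGeometry,
    envelope: PatientTableEnvelope,
    target: StructureVolume,
) -> bool:
    """True iff the divergent beam subtending the target enters or exits the
    patient envelope beyond the scanned CT extent (would irradiate through
    un-scanned anatomy).

    Rays are cast from the source through the corners of the target bounding
    box; the z-range (patient frame) of each ray's traversal of the envelope
    box is compared against ``ct_extent_mm``.
    """
    source, _, _, _ = beam_frame(geometry)
    iso = target.isocenter_mm
    corners = _target_corners(target) + iso
    box_lo = envelope.box_min_mm
    box_hi = envelope.box_max_mm
    src = source + iso  # patient-frame absolute coordinates
    dirs = corners - src
    ct_lo, ct_hi = envelope.ct_extent_mm

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (box_lo - src) / dirs
        t2 = (box_hi - src) / dirs
    tin = np.nanmax(np.minimum(t1, t2), axis=1)
    tout = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = tout > np.maximum(tin, 0.0)
    if not hit.any():
        return False
    z_in = src[2] + tin[hit] * dirs[hit, 2]
    z_out = src[2] + tout[hit] * dirs[hit, 2]
    z_min = np.minimum(z_in, z_out)
    z_max = np.maximum(z_in, z_out)
    return bool(np.any(z_min < ct_lo) or np.any(z_max > ct_hi))


@dataclass
class ExclusionGrid:
    """Per-cause exclusion labels over a (gantry, table) grid."""

    gantry_axis: np.ndarray
    table_axis: np.ndarray
    collision: np.ndarray
    ct_length: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.collision | self.ct_length


def exclusion_mask(
    gantry_axis: Iterable[float],
    table_axis: Iterable[float],
    clearance: LinacClearance,
    envelope: PatientTableEnvelope,
    target: StructureVolume,
) -> ExclusionGrid:
    """Cellwise OR of collision and CT-length exclusion with cause labels."""
    g_ax = np.asarray(list(gantry_axis), dtype=float)
    t_ax = np.asarray(list(table_axis), dtype=float)
    coll = np.zeros((len(g_ax), len(t_ax)), dtype=bool)
    ct = np.zeros_like(coll)
    for j, t in enumerate(t_ax):
        # collision radial/slab candidacy depends only on table angle; the
        # azimuth test per gantry angle is cheap, ct test is per-cell anyway
        for i, g in enumerate(g_ax):
            geom = BeamGeometry(gantry_deg=g, table_deg=t, sad_mm=clearance.sad_mm)
            coll[i, j] = collides(geom, clearance, envelope)
            ct[i, j] = ct_length_exclusion(geom, envelope, target)
    return ExclusionGrid(gantry_axis=g_ax, table_axis=t_ax, collision=coll, ct_length=ct)
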