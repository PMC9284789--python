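"""Synthetic phantoms, analytic dose distributions, and lagged delivery logs.

Everything here is a pure function of (spec, seed), so downstream modules are
testable without any external data.  Voxel membership rule: a voxel belongs
to a shape iff its *centre* lies inside the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .bev import StructureVolume
from .errors import DoseError, GeometryError
from .metrics import DoseGrid
from .pathfinding import TrajectoryPath

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "SyntheticPhantomSpec",
    "SyntheticDoseSpec",
    "make_phantom",
    "make_dose",
    "make_delivery_log",
    "default_hn_spec",
]


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: Tuple[float, float, float]
    semiaxes_mm: Tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = (pts - np.asarray(self.center_mm)) / np.asarray(self.semiaxes_mm)
        return (rel**2).sum(axis=-1) <= 1.0

    def contains_grid(self, axes: Sequence[np.ndarray]) -> np.ndarray:
        q = [((ax - c) / s) ** 2 for ax, c, s in zip(axes, self.center_mm, self.semiaxes_mm)]
        return q[0][:, None, None] + q[1][None, :, None] + q[2][None, None, :] <= 1.0

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        c, s = np.asarray(self.center_mm), np.asarray(self.semiaxes_mm)
        return c - s, c + s


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder with its axis along a grid axis (default z)."""

    center_mm: Tuple[float, float, float]
    radius_mm: float
    half_length_mm: float
    axis: int = 2

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - np.asarray(self.center_mm)
        radial_axes = [a for a in range(3) if a != self.axis]
        r2 = rel[..., radial_axes[0]] ** 2 + rel[..., radial_axes[1]] ** 2
        return (r2 <= self.radius_mm**2) & (np.abs(rel[..., self.axis]) <= self.half_length_mm)

    def contains_grid(self, axes: Sequence[np.ndarray]) -> np.ndarray:
        rel = [ax - c for ax, c in zip(axes, self.center_mm)]
        ra = [a for a in range(3) if a != self.axis]
        shape = [1, 1, 1]
        parts = []
        for a in range(3):
            s = shape.copy()
            s[a] = -1
            parts.append(rel[a].reshape(s))
        r2 = parts[ra[0]] ** 2 + parts[ra[1]] ** 2
        return (r2 <= self.radius_mm**2) & (np.abs(parts[self.axis]) <= self.half_length_mm)

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        ext = np.full(3, self.radius_mm)
        ext[self.axis] = self.half_length_mm
        return c - ext, c + ext


Shape = Union[Ellipsoid, Cylinder]


@dataclass
class SyntheticPhantomSpec:
    grid_shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]
    target: Tuple[str, Shape]
    oars: Sequence[Tuple[str, Shape, str]] = ()  # (name, shape, "serial"|"parallel")
    body: Optional[Shape] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")

    @property
    def origin_mm(self) -> np.ndarray:
        """Centre of voxel (0,0,0); the isocenter sits at the grid centre."""
        shape = np.asarray(self.grid_shape, float)
        sp = np.asarray(self.spacing_mm, float)
        return -(shape - 1) / 2.0 * sp

    def grid_extent_mm(self) -> Tuple[np.ndarray, np.ndarray]:
        sp = np.asarray(self.spacing_mm, float)
        lo = self.origin_mm - sp / 2.0
        hi = self.origin_mm + (np.asarray(self.grid_shape) - 0.5) * sp
        return lo, hi


@dataclass
class SyntheticDoseSpec:
    mode: str  # "uniform" | "spherical-falloff" | "linear-gradient"
    plateau_gy: float
    center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    gradient_pct_per_mm: float = 0.0   # linear-gradient: % of plateau lost per mm
    gradient_axis: int = 0
    falloff_radius_mm: float = 25.0    # spherical-falloff: plateau inside, falloff beyond
    falloff_pct_per_mm: float = 5.0
    prescription_gy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.plateau_gy < 0:
            raise DoseError("invalid dose: negative plateau")
        if self.mode not in ("uniform", "spherical-falloff", "linear-gradient"):
            raise DoseError(f"invalid dose: unknown mode {self.mode!r}")


def _grid_axes(spec: SyntheticPhantomSpec) -> List[np.ndarray]:
    sp = np.asarray(spec.spacing_mm, float)
    return [spec.origin_mm[a] + np.arange(spec.grid_shape[a]) * sp[a] for a in range(3)]


def _check_inside(name: str, shape: Shape, spec: SyntheticPhantomSpec) -> None:
    lo, hi = shape.bounds()
    glo, ghi = spec.grid_extent_mm()
    if np.any(lo < glo) or np.any(hi > ghi):
        raise GeometryError(f"geometry out of bounds: {name!r} exceeds the grid")


def make_phantom(spec: SyntheticPhantomSpec) -> Dict[str, StructureVolume]:
    """Voxelize all shapes of the spec onto one shared grid.

    Returns an ordered mapping name -> StructureVolume (target first, then
    OARs, then body).  Deterministic given the spec.
    """
    axes = _grid_axes(spec)
    structures: Dict[str, StructureVolume] = {}

    def add(name: str, shape: Shape, role: str) -> None:
        _check_inside(name, shape, spec)
        mask = shape.contains_grid(axes)
        structures[name] = StructureVolume(
            name=name,
            role=role,
            mask=mask,
            spacing_mm=np.asarray(spec.spacing_mm, float),
            origin_mm=spec.origin_mm,
            isocenter_mm=np.zeros(3),
        )

    tname, tshape = spec.target
    add(tname, tshape, "target")
    for name, shape, _tag in spec.oars:
        add(name, shape, "oar")
    if spec.body is not None:
        add("body", spec.body, "body")
    return structures


def default_hn_spec(spacing_mm: float = 2.0, seed: int = 0) -> SyntheticPhantomSpec:
    """Head-and-neck-like phantom: spherical target at the isocenter, two
    lateral parallel 'parotid-like' ellipsoids, a posterior serial
    'cord-like' cylinder, inside a body ellipsoid.

    The lateral OARs make the GT cost structure asymmetric in table angle, so
    a non-coplanar path can beat the coplanar one.
    """
    sp = float(spacing_mm)
    shape = (int(round(192 / sp)), int(round(232 / sp)), int(round(312 / sp)))
    return SyntheticPhantomSpec(
        grid_shape=shape,
        spacing_mm=(sp, sp, sp),
        target=("ptv", Ellipsoid((0.0, 0.0, 0.0), (25.0, 25.0, 25.0))),
        oars=[
            ("parotid_l", Ellipsoid((45.0, 0.0, 0.0), (15.0, 15.0, 15.0)), "parallel"),
            ("parotid_r", Ellipsoid((-45.0, 0.0, 0.0), (15.0, 15.0, 15.0)), "parallel"),
            ("cord", Cylinder((0.0, -50.0, 0.0), 5.0, 60.0, axis=2), "serial"),
        ],
        body=Ellipsoid((0.0, 0.0, 0.0), (90.0, 110.0, 150.0)),
        seed=seed,
    )


def make_dose(spec: SyntheticDoseSpec, grid: StructureVolume) -> DoseGrid:
    """Analytic dose on the grid of ``grid`` (any structure of the phantom).

    * ``uniform``: constant plateau everywhere.
    * ``linear-gradient``: plateau at the stated centre along the gradient
      axis, dropping ``gradient_pct_per_mm`` percent of the plateau per mm of
      signed distance, clipped at 0.
    * ``spherical-falloff``: plateau inside ``falloff_radius_mm`` of the
      centre, then linear falloff of ``falloff_pct_per_mm`` %/mm, clipped.
    """
    sp = grid.spacing_mm
    axes = [grid.origin_mm[a] - grid.isocenter_mm[a] + np.arange(grid.mask.shape[a]) * sp[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    c = np.asarray(spec.center_mm)
    if spec.mode == "uniform":
        dose = np.full(grid.mask.shape, spec.plateau_gy)
    elif spec.mode == "linear-gradient":
        dist = pts[..., spec.gradient_axis] - c[spec.gradient_axis]
        dose = spec.plateau_gy * (1.0 - spec.gradient_pct_per_mm / 100.0 * dist)
    else:  # spherical-falloff
        r = np.linalg.norm(pts - c, axis=-1)
        beyond = np.clip(r - spec.falloff_radius_mm, 0.0, None)
        dose = spec.plateau_gy * (1.0 - spec.falloff_pct_per_mm / 100.0 * beyond)
    dose = np.clip(dose, 0.0, None)
    return DoseGrid(
        dose=dose,
        spacing_mm=sp.copy(),
        origin_mm=grid.origin_mm.copy(),
        prescription_gy=spec.prescription_gy if spec.prescription_gy is not None else spec.plateau_gy,
    )


def make_delivery_log(
    path: TrajectoryPath,
    lag_gain: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    gantry_speed_deg_s: float = 6.0,
    include_jaws_as_leaves: bool = False,
) -> pd.DataFrame:
    """Simulated machine log: each axis lags its expected value in
    proportion to its speed, plus Gaussian noise.

    ``actual = expected - lag_gain * speed + N(0, noise_sd)``, with the speed
    taken as the finite-difference derivative of the expected trace over the
    timestamps (gantry moving at ``gantry_speed_deg_s``).  Deterministic
    given the seed.
    """
    if len(path) < 2:
        raise ValueError("path needs at least 2 control points")
    rng = np.random.default_rng(seed)
    dg = np.abs(np.diff(path.gantry_deg))
    t = np.concatenate([[0.0], np.cumsum(dg / gantry_speed_deg_s)])
    log = pd.DataFrame({"timestamp": t})
    axes = {
        "gantry": path.gantry_deg,
        "table": path.table_deg,
        "collimator": path.collimator_deg,
    }
    if include_jaws_as_leaves:
        axes["leaf_0"] = path.jaw_x1_mm
        axes["leaf_1"] = path.jaw_x2_mm
    for name, expected in axes.items():
        expected = np.asarray(expected, float)
        speed = np.gradient(expected, t)
        actual = expected - lag_gain * speed + rng.normal(0.0, noise_sd, size=len(expected))
        log[f"{name}_expected"] = expected
        log[f"{name}_actual"] = actual
    return log
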