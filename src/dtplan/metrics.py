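"""DVH computation and plan-quality endpoints: D_x%, D_0.03cc, V_x, mean
dose, Paddick conformity index, and the 95%/105% homogeneity index
(HI = V_95% - V_105%, in percent of target volume).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .bev import StructureVolume
from .errors import DoseError, EmptyStructureError

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "dvh",
    "endpoint_Dx",
    "endpoint_D_cc",
    "endpoint_Vx",
    "mean_dose",
    "normalize",
    "ci_paddick",
    "hi95",
    "resample_dose",
    "plan_metrics_report",
]


@dataclass
class DoseGrid:
    """Scalar dose (Gy) on a regular grid; same frame conventions as
    StructureVolume."""

    dose: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    prescription_gy: float

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if np.any(self.dose < 0):
            raise DoseError("invalid dose: negative values")
        if self.prescription_gy <= 0:
            raise DoseError("invalid dose: non-positive prescription")


@dataclass
class DVHCurve:
    """Cumulative DVH sampled exactly at the voxel dose order statistics.

    ``samples`` keeps the raw per-voxel doses so endpoints can be computed
    without re-binning error.
    """

    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    samples: np.ndarray
    voxel_volume_mm3: float


def _structure_doses(dose: DoseGrid, structure: StructureVolume) -> np.ndarray:
    if dose.dose.shape != structure.mask.shape:
        raise DoseError(
            "invalid dose: dose grid does not match the structure grid; resample first"
        )
    if not structure.mask.any():
        raise EmptyStructureError(f"empty structure: {structure.name!r}")
    return dose.dose[structure.mask]


def dvh(dose: DoseGrid, structure: StructureVolume) -> DVHCurve:
    """Cumulative DVH over the structure's voxels (volume = count x voxel
    volume); starts at 1 at dose 0 and is non-increasing."""
    d = np.sort(_structure_doses(dose, structure))
    n = len(d)
    axis = np.concatenate([[0.0], d])
    # fraction of voxels with dose >= axis value
    frac = np.concatenate([[1.0], (n - np.searchsorted(d, d, side="left")) / n])
    return DVHCurve(
        dose_gy=axis,
        volume_fraction=frac,
        samples=d,
        voxel_volume_mm3=structure.voxel_volume_mm3,
    )


def endpoint_Dx(curve: DVHCurve, x_percent: float) -> float:
    """Dose received by at least x% of the structure volume, linearly
    interpolated between bracketing order statistics (equivalent to the
    (100-x)th linear-interpolation percentile of the voxel doses)."""
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    return float(np.percentile(curve.samples, 100.0 - x_percent, method="linear"))


def endpoint_D_cc(dose: DoseGrid, structure: StructureVolume, cc: float = 0.03) -> float:
    """Minimum dose in the hottest ``cc`` cm^3, interpolating within the last
    (partial) voxel."""
    d = np.sort(_structure_doses(dose, structure))[::-1]
    vox_cc = structure.voxel_volume_mm3 / 1000.0
    total_cc = len(d) * vox_cc
    if cc > total_cc:
        raise DoseError(f"volume exceeds structure: {cc} cc > {total_cc:.3f} cc")
    if cc <= 0:
        raise ValueError("cc must be positive")
    cum = vox_cc * np.arange(1, len(d) + 1)
    return float(np.interp(cc, cum, d, left=d[0]))


def endpoint_Vx(curve: DVHCurve, threshold_gy: float) -> float:
    """Fraction of structure volume receiving at least ``threshold_gy``."""
    return float((curve.samples >= threshold_gy).mean())


def mean_dose(dose: DoseGrid, structure: StructureVolume) -> float:
    return float(_structure_doses(dose, structure).mean())


def normalize(dose: DoseGrid, target: StructureVolume, rule: str = "D95->100%") -> DoseGrid:
    """Scale the whole dose grid by one factor so the normalization rule
    holds exactly.

    Rules: ``"D95->100%"`` (target D95% becomes 100% of prescription) and
    ``"D97->99%"`` (target D97% becomes 99% of prescription).
    """
    rules = {"D95->100%": (95.0, 1.00), "D97->99%": (97.0, 0.99)}
    if rule not in rules:
        raise ValueError(f"unknown normalization rule {rule!r}")
    x, level = rules[rule]
    current = endpoint_Dx(dvh(dose, target), x)
    if current <= 0:
        raise DoseError("degenerate dose: normalization endpoint is zero")
    factor = level * dose.prescription_gy / current
    return replace(dose, dose=dose.dose * factor)


def ci_paddick(
    dose: DoseGrid, target: StructureVolume, prescription_gy: Optional[float] = None
) -> float:
    """Paddick conformity index TV_PIV^2 / (TV * PIV); 0 when nothing
    receives the prescription."""
    if not target.mask.any():
        raise EmptyStructureError(f"empty structure: {target.name!r}")
    if dose.dose.shape != target.mask.shape:
        raise DoseError("invalid dose: grid mismatch; resample first")
    rx = prescription_gy if prescription_gy is not None else dose.prescription_gy
    piv = dose.dose >= rx
    tv = float(target.mask.sum())
    piv_n = float(piv.sum())
    if piv_n == 0:
        return 0.0
    tv_piv = float((piv & target.mask).sum())
    return tv_piv**2 / (tv * piv_n)


def hi95(
    dose: DoseGrid, target: StructureVolume, prescription_gy: Optional[float] = None
) -> float:
    """Homogeneity index V_95%Rx - V_105%Rx over the target, in percent."""
    rx = prescription_gy if prescription_gy is not None else dose.prescription_gy
    d = _structure_doses(dose, target)
    v95 = (d >= 0.95 * rx).mean()
    v105 = (d >= 1.05 * rx).mean()
    return float(100.0 * (v95 - v105))


def resample_dose(dose: DoseGrid, like: StructureVolume) -> DoseGrid:
    """Trilinear resampling of the dose grid onto a structure's grid (used
    when the dose engine grid differs from the CT grid)."""
    shape = like.mask.shape
    idx = np.indices(shape, dtype=float)
    mm = [like.origin_mm[a] + idx[a] * like.spacing_mm[a] for a in range(3)]
    coords = np.stack(
        [(mm[a] - dose.origin_mm[a]) / dose.spacing_mm[a] for a in range(3)]
    )
    out = map_coordinates(dose.dose, coords, order=1, mode="nearest")
    return DoseGrid(
        dose=out,
        spacing_mm=like.spacing_mm.copy(),
        origin_mm=like.origin_mm.copy(),
        prescription_gy=dose.prescription_gy,
    )


def plan_metrics_report(
    dose: DoseGrid,
    structures: Dict[str, StructureVolume],
    target_name: str,
    dx_percents=(95.0, 50.0, 2.0),
    vx_gy=(),
) -> Dict:
    """JSON-serialisable per-structure endpoint summary plus target CI/HI."""
    report: Dict = {"prescription_gy": dose.prescription_gy, "structures": {}}
    for name, s in structures.items():
        if not s.mask.any():
            continue
        curve = dvh(dose, s)
        entry = {
            "mean_gy": mean_dose(dose, s),
            "d_0.03cc_gy": endpoint_D_cc(dose, s, min(0.03, s.voxel_count * s.voxel_volume_mm3 / 1000.0)),
        }
        for x in dx_percents:
            entry[f"d{x:g}%_gy"] = endpoint_Dx(curve, x)
        for v in vx_gy:
            entry[f"v{v:g}gy"] = endpoint_Vx(curve, v)
        report["structures"][name] = entry
    target = structures[target_name]
    report["ci_paddick"] = ci_paddick(dose, target)
    report["hi95_percent"] = hi95(dose, target)
    return report
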