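"""Global gamma-index comparison of two dose distributions.

gamma(r) = min over evaluated positions r' of
    sqrt( (|r - r'| / DTA)^2 + ((D_eval(r') - D_ref(r)) / dD)^2 )

with dD = dose tolerance as a percent of the *reference* maximum (global
normalisation).  Points where the reference dose is below the low-dose
threshold are excluded from the passing-rate denominator.  The search is a
lattice of offsets at ``search_step_fraction * DTA`` spacing within
``search_radius_factor * DTA``, with linear interpolation of the evaluated
dose and early termination once the spatial term alone exceeds every
point's current minimum.
Works for 1D, 2D and 3D grids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DoseError
from .metrics import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "passing_rate"]


@dataclass(frozen=True)
class GammaCriteria:
    dose_tolerance_percent_of_max: float = 2.0
    distance_to_agreement_mm: float = 2.0
    low_dose_threshold_percent_of_max: float = 10.0
    search_radius_factor: float = 3.0
    search_step_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "dose_tolerance_percent_of_max",
            "distance_to_agreement_mm",
            "low_dose_threshold_percent_of_max",
            "search_radius_factor",
            "search_step_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GammaResult:
    gamma: np.ndarray          # per reference point; NaN where not computable
    evaluated_mask: np.ndarray  # reference points above the low-dose threshold
    criteria: GammaCriteria

    def summary(self) -> dict:
        return {
            "passing_rate_percent": passing_rate(self),
            "n_evaluated": int(self.evaluated_mask.sum()),
            "n_passing": int((self.gamma[self.evaluated_mask] <= 1.0).sum()),
            "criteria": {
                "dose_percent": self.criteria.dose_tolerance_percent_of_max,
                "distance_mm": self.criteria.distance_to_agreement_mm,
                "threshold_percent": self.criteria.low_dose_threshold_percent_of_max,
            },
        }


def _as_nd(dose: DoseGrid):
    arr = np.asarray(dose.dose, float)
    nd = arr.ndim
    spacing = np.broadcast_to(np.atleast_1d(dose.spacing_mm), (nd,)).astype(float)
    origin = np.broadcast_to(np.atleast_1d(dose.origin_mm), (nd,)).astype(float)
    return arr, spacing, origin


def gamma_map(
    reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Gamma index at every reference grid point against the evaluated
    distribution (grids may differ; coordinates are reconciled in mm)."""
    ref, ref_sp, ref_or = _as_nd(reference)
    ev, ev_sp, ev_or = _as_nd(evaluated)
    if ref.ndim != ev.ndim:
        raise DoseError("invalid dose: dimensionality mismatch")
    ref_hi = ref_or + (np.array(ref.shape) - 1) * ref_sp
    ev_hi = ev_or + (np.array(ev.shape) - 1) * ev_sp
    if np.any(ref_hi < ev_or) or np.any(ev_hi < ref_or):
        raise DoseError("no overlap between reference and evaluated grids")

    dta = criteria.distance_to_agreement_mm
    d_max = float(ref.max())
    if d_max <= 0:
        raise DoseError("invalid dose: reference maximum is zero")
    dd = criteria.dose_tolerance_percent_of_max / 100.0 * d_max
    threshold = criteria.low_dose_threshold_percent_of_max / 100.0 * d_max

    # reference point coordinates (mm), flattened
    idx = np.indices(ref.shape, dtype=float).reshape(ref.ndim, -1)
    mm = idx * ref_sp[:, None] + ref_or[:, None]
    ref_flat = ref.reshape(-1)

    # offset lattice sorted by radius
    step = criteria.search_step_fraction * dta
    radius = criteria.search_radius_factor * dta
    k = int(np.floor(radius / step))
    axes = [np.arange(-k, k + 1) * step] * ref.ndim
    offsets = np.array(list(itertools.product(*axes)))
    norms = np.linalg.norm(offsets, axis=1)
    keep = norms <= radius + 1e-12
    offsets, norms = offsets[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    offsets, norms = offsets[order], norms[order]

    gamma2 = np.full(ref_flat.shape, np.inf)
    for off, r in zip(offsets, norms):
        spatial2 = (r / dta) ** 2
        worst = gamma2.max()
        if spatial2 >= worst:
            break
        coords = (mm + off[:, None] - ev_or[:, None]) / ev_sp[:, None]
        d_eval = map_coordinates(ev, coords, order=1, mode="constant", cval=np.nan)
        cand = spatial2 + ((d_eval - ref_flat) / dd) ** 2
        gamma2 = np.fmin(gamma2, cand)

    gamma = np.sqrt(gamma2).reshape(ref.shape)
    gamma[np.isinf(gamma)] = np.nan
    evaluated_mask = (ref >= threshold) & np.isfinite(gamma)
    return GammaResult(gamma=gamma, evaluated_mask=evaluated_mask, criteria=criteria)


def passing_rate(result: GammaResult) -> float:
    """Percent of above-threshold reference points with gamma <= 1."""
    n = int(result.evaluated_mask.sum())
    if n == 0:
        raise DoseError("nothing above threshold: no evaluated points")
    return float(100.0 * (result.gamma[result.evaluated_mask] <= 1.0).sum() / n)
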