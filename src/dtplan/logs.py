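"""Delivery-log accuracy analysis: expected-vs-actual deviations per dynamic
axis, RMS/maximum statistics, and the Pearson correlation between axis speed
and deviation.

Logs are plain tables (pandas DataFrame / CSV): one row per control point
with a ``timestamp`` column (seconds) and ``<axis>_expected`` /
``<axis>_actual`` column pairs.  MLC leaves use axis names ``leaf_<i>`` and
are summarised as mean/max of the per-leaf RMS.  Angular axes (gantry,
table, collimator) use the shortest signed angular difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LogError

__all__ = [
    "ANGULAR_AXES",
    "axis_deviations",
    "axis_speed",
    "AxisAccuracy",
    "AxisAccuracyReport",
    "accuracy_report",
    "read_log_csv",
    "write_log_csv",
]

ANGULAR_AXES = frozenset({"gantry", "table", "collimator"})


def _axes_in(log: pd.DataFrame) -> List[str]:
    return sorted(
        c[: -len("_expected")]
        for c in log.columns
        if c.endswith("_expected") and f"{c[:-len('_expected')]}_actual" in log.columns
    )


def _check_log(log: pd.DataFrame) -> None:
    if "timestamp" not in log.columns:
        raise LogError("invalid log: missing timestamp column")
    t = log["timestamp"].to_numpy(float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise LogError("invalid log: timestamps not strictly increasing")


def axis_deviations(log: pd.DataFrame, axis: str) -> np.ndarray:
    """actual - expected per control point (wrapped for angular axes)."""
    _check_log(log)
    if axis not in _axes_in(log):
        raise LogError(f"unknown axis: {axis!r}")
    dev = log[f"{axis}_actual"].to_numpy(float) - log[f"{axis}_expected"].to_numpy(float)
    if axis in ANGULAR_AXES:
        dev = (dev + 180.0) % 360.0 - 180.0
    return dev


def axis_speed(log: pd.DataFrame, axis: str) -> np.ndarray:
    """Finite-difference speed of the *expected* trace (central differences,
    one-sided at the ends)."""
    _check_log(log)
    if axis not in _axes_in(log):
        raise LogError(f"unknown axis: {axis!r}")
    if len(log) < 2:
        raise LogError("invalid log: need at least 2 records for speed")
    t = log["timestamp"].to_numpy(float)
    x = log[f"{axis}_expected"].to_numpy(float)
    if axis in ANGULAR_AXES:
        x = np.rad2deg(np.unwrap(np.deg2rad(x)))
    return np.gradient(x, t)


@dataclass
class AxisAccuracy:
    rms: float
    max_abs: float
    speed_deviation_r: Optional[float]  # None when undefined (zero variance)
    speed_deviation_p: Optional[float]

    def to_dict(self) -> dict:
        return {
            "rms": self.rms,
            "max_abs": self.max_abs,
            "speed_deviation_r": self.speed_deviation_r,
            "speed_deviation_p": self.speed_deviation_p,
        }


@dataclass
class AxisAccuracyReport:
    axes: Dict[str, AxisAccuracy]
    mlc_mean_rms: Optional[float] = None
    mlc_max_rms: Optional[float] = None

    def to_dict(self) -> dict:
        out = {name: acc.to_dict() for name, acc in self.axes.items()}
        if self.mlc_mean_rms is not None:
            out["mlc"] = {"mean_rms": self.mlc_mean_rms, "max_rms": self.mlc_max_rms}
        return out


def _pearson(speed: np.ndarray, dev: np.ndarray):
    if np.std(speed) == 0 or np.std(dev) == 0:
        return None, None
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        r, p = stats.pearsonr(speed, dev)
    return float(r), float(p)


def accuracy_report(log: pd.DataFrame) -> AxisAccuracyReport:
    """Per-axis RMS/max deviation and speed-deviation correlation; MLC
    leaves summarised as mean and max of per-leaf RMS (moving leaves only)."""
    _check_log(log)
    axes: Dict[str, AxisAccuracy] = {}
    leaf_rms: List[float] = []
    for axis in _axes_in(log):
        dev = axis_deviations(log, axis)
        rms = float(np.sqrt(np.mean(dev**2)))
        if axis.startswith("leaf_"):
            expected = log[f"{axis}_expected"].to_numpy(float)
            if np.ptp(expected) > 0:  # moving leaves only
                leaf_rms.append(rms)
            continue
        speed = axis_speed(log, axis)
        r, p = _pearson(speed, dev)
        axes[axis] = AxisAccuracy(rms=rms, max_abs=float(np.max(np.abs(dev))), speed_deviation_r=r, speed_deviation_p=p)
    report = AxisAccuracyReport(axes=axes)
    if leaf_rms:
        report.mlc_mean_rms = float(np.mean(leaf_rms))
        report.mlc_max_rms = float(np.max(leaf_rms))
    return report


def read_log_csv(path) -> pd.DataFrame:
    log = pd.read_csv(path)
    _check_log(log)
    return log


def write_log_csv(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)
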