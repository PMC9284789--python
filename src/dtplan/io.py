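"""Readers, writers and run configuration.

Volumes are NIfTI (.nii / .nii.gz via nibabel) with a JSON sidecar carrying
names, roles, spacing, origin and isocenter; trajectories are CSV (one row
per control point) plus a JSON twin; cost maps and reports are JSON.  A
simple JSON polygon-contour format is supported as a light-weight stand-in
for DICOM-RT structure sets and rasterised with the voxel-centre-in-polygon
rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath

from .bev import StructureVolume
from .collision import LinacClearance, PatientTableEnvelope
from .costmap import GantryTableMap, PathRecipe
from .errors import ConfigError
from .gamma import GammaCriteria
from .metrics import DoseGrid
from .pathfinding import TrajectoryPath
from .pipeline import PlanSettings

__all__ = [
    "RunConfig",
    "load_config",
    "write_structures",
    "read_structures",
    "write_dose",
    "read_dose",
    "read_contours_json",
    "rasterize_polygon_slices",
    "write_trajectory",
    "read_trajectory",
    "write_gt_map",
    "read_gt_map",
    "plot_gt_map",
]


# ---------------------------------------------------------------------------
# volumes


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_structures(structures: Dict[str, StructureVolume], out_dir) -> Path:
    """Write one NIfTI per structure plus a ``structures.json`` sidecar;
    returns the sidecar path."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar: Dict = {"structures": {}}
    for name, s in structures.items():
        fname = f"{name}.nii.gz"
        img = nib.Nifti1Image(s.mask.astype(np.uint8), _affine(s.spacing_mm, s.origin_mm))
        nib.save(img, out_dir / fname)
        sidecar["structures"][name] = {
            "file": fname,
            "role": s.role,
            "spacing_mm": s.spacing_mm.tolist(),
            "origin_mm": s.origin_mm.tolist(),
            "isocenter_mm": s.isocenter_mm.tolist(),
        }
    path = out_dir / "structures.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def read_structures(sidecar_path) -> Dict[str, StructureVolume]:
    import nibabel as nib

    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    out: Dict[str, StructureVolume] = {}
    for name, entry in meta["structures"].items():
        if "role" not in entry:
            raise ConfigError(f"missing role for structure {name!r}")
        img = nib.load(sidecar_path.parent / entry["file"])
        out[name] = StructureVolume(
            name=name,
            role=entry["role"],
            mask=np.asarray(img.dataobj) > 0,
            spacing_mm=np.asarray(entry["spacing_mm"], float),
            origin_mm=np.asarray(entry["origin_mm"], float),
            isocenter_mm=np.asarray(entry.get("isocenter_mm", [0, 0, 0]), float),
        )
    return out


def write_dose(dose: DoseGrid, path) -> None:
    import nibabel as nib

    path = Path(path)
    nib.save(nib.Nifti1Image(dose.dose, _affine(dose.spacing_mm, dose.origin_mm)), path)
    meta = {
        "prescription_gy": dose.prescription_gy,
        "spacing_mm": dose.spacing_mm.tolist(),
        "origin_mm": dose.origin_mm.tolist(),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_dose(path) -> DoseGrid:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return DoseGrid(
        dose=np.asarray(img.dataobj, dtype=float),
        spacing_mm=np.asarray(meta["spacing_mm"], float),
        origin_mm=np.asarray(meta["origin_mm"], float),
        prescription_gy=float(meta["prescription_gy"]),
    )


# ---------------------------------------------------------------------------
# polygon contours (DICOM-RT-like, but plain JSON)


def rasterize_polygon_slices(
    contours: List[dict], grid_shape, spacing_mm, origin_mm
) -> np.ndarray:
    """Rasterize per-slice (x, y) polygons into a 3D mask.

    Each contour is ``{"z_index": int, "points_mm": [[x, y], ...]}``; a voxel
    belongs to the polygon iff its centre lies inside.
    """
    spacing_mm = np.asarray(spacing_mm, float)
    origin_mm = np.asarray(origin_mm, float)
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    xs = origin_mm[0] + np.arange(grid_shape[0]) * spacing_mm[0]
    ys = origin_mm[1] + np.arange(grid_shape[1]) * spacing_mm[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    for contour in contours:
        z = int(contour["z_index"])
        poly = MplPath(np.asarray(contour["points_mm"], float))
        inside = poly.contains_points(pts).reshape(len(xs), len(ys))
        mask[:, :, z] |= inside
    return mask


def read_contours_json(path) -> StructureVolume:
    """Read a JSON polygon structure set and rasterize it."""
    meta = json.loads(Path(path).read_text())
    mask = rasterize_polygon_slices(
        meta["contours"], meta["grid_shape"], meta["spacing_mm"], meta["origin_mm"]
    )
    return StructureVolume(
        name=meta["name"],
        role=meta["role"],
        mask=mask,
        spacing_mm=np.asarray(meta["spacing_mm"], float),
        origin_mm=np.asarray(meta["origin_mm"], float),
        isocenter_mm=np.asarray(meta.get("isocenter_mm", [0, 0, 0]), float),
    )


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(path: TrajectoryPath, out_csv) -> None:
    out_csv = Path(out_csv)
    df = pd.DataFrame(
        {
            "index": np.arange(len(path)),
            "gantry_deg": path.gantry_deg,
            "table_deg": path.table_deg,
            "collimator_deg": path.collimator_deg,
            "jaw_x1_mm": path.jaw_x1_mm,
            "jaw_x2_mm": path.jaw_x2_mm,
        }
    )
    df.to_csv(out_csv, index=False)
    meta = {"name": path.name, "duplication": path.duplication}
    out_csv.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trajectory(csv_path) -> TrajectoryPath:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrajectoryPath(
        gantry_deg=df["gantry_deg"].to_numpy(),
        table_deg=df["table_deg"].to_numpy(),
        collimator_deg=df["collimator_deg"].to_numpy(),
        jaw_x1_mm=df["jaw_x1_mm"].to_numpy(),
        jaw_x2_mm=df["jaw_x2_mm"].to_numpy(),
        name=meta.get("name", csv_path.stem),
        duplication=meta.get("duplication", "none"),
    )


# ---------------------------------------------------------------------------
# GT maps


def write_gt_map(gt_map: GantryTableMap, path) -> None:
    payload = {
        "gantry_axis": gt_map.gantry_axis.tolist(),
        "table_axis": gt_map.table_axis.tolist(),
        "weights": gt_map.weights,
        "per_oar_layers": {k: v.tolist() for k, v in gt_map.per_oar_layers.items()},
        "combined": gt_map.combined.tolist(),
    }
    if gt_map.exclusions is not None:
        payload["exclusion_collision"] = gt_map.exclusions.collision.tolist()
        payload["exclusion_ct_length"] = gt_map.exclusions.ct_length.tolist()
    Path(path).write_text(json.dumps(payload))


def read_gt_map(path) -> GantryTableMap:
    from .collision import ExclusionGrid

    payload = json.loads(Path(path).read_text())
    g_ax = np.asarray(payload["gantry_axis"], float)
    t_ax = np.asarray(payload["table_axis"], float)
    excl = None
    if "exclusion_collision" in payload:
        excl = ExclusionGrid(
            gantry_axis=g_ax,
            table_axis=t_ax,
            collision=np.asarray(payload["exclusion_collision"], bool),
            ct_length=np.asarray(payload["exclusion_ct_length"], bool),
        )
    return GantryTableMap(
        gantry_axis=g_ax,
        table_axis=t_ax,
        per_oar_layers={k: np.asarray(v, float) for k, v in payload["per_oar_layers"].items()},
        weights={k: float(v) for k, v in payload["weights"].items()},
        combined=np.asarray(payload["combined"], float),
        exclusions=excl,
    )


def plot_gt_map(gt_map: GantryTableMap, out_png, path_table_deg=None) -> None:
    """Heatmap of the combined cost with grey shading for exclusion zones
    (light grey: collision, dark grey: CT-length)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    extent = (
        gt_map.gantry_axis[0],
        gt_map.gantry_axis[-1],
        gt_map.table_axis[0],
        gt_map.table_axis[-1],
    )
    ax.imshow(
        gt_map.combined.T, origin="lower", aspect="auto", extent=extent, cmap="viridis"
    )
    if gt_map.exclusions is not None:
        for grid, color in ((gt_map.exclusions.collision, "0.8"), (gt_map.exclusions.ct_length, "0.4")):
            overlay = np.ma.masked_where(~grid.T, np.ones_like(grid.T, dtype=float))
            ax.imshow(overlay, origin="lower", aspect="auto", extent=extent,
                      cmap=matplotlib.colors.ListedColormap([color]), vmin=0, vmax=1)
    if path_table_deg is not None:
        ax.plot(gt_map.gantry_axis, path_table_deg, "r-", lw=1.5)
    ax.set_xlabel("gantry angle (deg)")
    ax.set_ylabel("table angle (deg)")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the published protocol values
    (2 deg control-point spacing, 3 deg/deg gradient limit, 10-point
    smoothing window, 2 cm safety margin, 2%/2 mm/10% gamma criteria)."""

    case: str = "case"
    seed: int = 0
    prescription_gy: float = 50.0
    normalization: str = "D95->100%"
    settings: PlanSettings = field(default_factory=PlanSettings)
    recipes: List[PathRecipe] = field(default_factory=list)
    gamma: GammaCriteria = field(default_factory=GammaCriteria)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    settings_raw = dict(raw.get("settings", {}))
    clearance = settings_raw.pop("clearance", None)
    envelope = settings_raw.pop("envelope", None)
    settings = PlanSettings(**settings_raw)
    if clearance is not None:
        settings.clearance = LinacClearance(**clearance)
    if envelope is not None:
        envelope = dict(envelope)
        if "ct_extent_mm" in envelope:
            envelope["ct_extent_mm"] = tuple(envelope["ct_extent_mm"])
        settings.envelope = PatientTableEnvelope(**envelope)
    recipes = [
        PathRecipe(
            name=r["name"],
            oar_names=list(r["oars"]),
            strategy=r.get("strategy", "none"),
            weights=r.get("weights"),
        )
        for r in raw.get("paths", [])
    ]
    gamma = GammaCriteria(**raw.get("gamma", {}))
    return RunConfig(
        case=raw.get("case", "case"),
        seed=int(raw.get("seed", 0)),
        prescription_gy=float(raw.get("prescription_gy", 50.0)),
        normalization=raw.get("normalization", "D95->100%"),
        settings=settings,
        recipes=recipes,
        gamma=gamma,
    )
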