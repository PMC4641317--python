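"""On-disk artefacts: NIfTI volumes, CSV metric reports, YAML configuration.

Masks are stored as unsigned 8-bit NIfTI, dose as 32-bit float NIfTI. Only
axis-aligned grids are supported: an oblique affine is rejected rather than
resampled, so round-trips are exact. Axes stored with a negative step are
flipped on read so that in-memory spacing is always positive.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grids import DoseGrid, StructureMask, VoxelGrid

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "write_metrics_report",
    "write_dvh_table",
    "load_yaml_config",
    "dump_yaml_config",
]


def _grid_and_data_from_nifti(path: str | os.PathLike) -> tuple[VoxelGrid, np.ndarray]:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D with shape {data.shape}"
        )
    aff = np.asarray(img.affine, dtype=float)
    lin = aff[:3, :3]
    if abs(np.linalg.det(lin)) < 1e-12:
        raise ValueError(f"{path}: affine is singular")
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-6 * np.abs(np.diag(lin)).max():
        raise ValueError(
            f"{path}: oblique affine not supported; only axis-aligned grids are accepted"
        )
    step = np.diag(lin).copy()
    origin = aff[:3, 3].copy()
    # normalise negative steps by flipping the corresponding array axis
    for ax in range(3):
        if step[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + step[ax] * (data.shape[ax] - 1)
            step[ax] = -step[ax]
    grid = VoxelGrid(origin=tuple(origin), spacing=tuple(step), dims=data.shape)
    return grid, np.ascontiguousarray(data)


def read_mask(path: str | os.PathLike, name: str | None = None) -> StructureMask:
    """Read a binary structure mask from a NIfTI volume.

    Any non-zero voxel value counts as occupied. The grid is taken from the
    affine; oblique affines are rejected.
    """
    grid, data = _grid_and_data_from_nifti(path)
    if name is None:
        base = os.path.basename(os.fspath(path))
        for suffix in (".nii.gz", ".nii"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
                break
        name = base
    return StructureMask(name=name, grid=grid, occupancy=data != 0)


def write_mask(mask: StructureMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.grid.affine())
    nib.save(img, os.fspath(path))


def read_dose(path: str | os.PathLike) -> DoseGrid:
    """Read a dose grid (Gy) from a NIfTI volume; values must be >= 0."""
    grid, data = _grid_and_data_from_nifti(path)
    data = data.astype(float)
    n_neg = int((data < 0).sum())
    if n_neg:
        raise ValueError(f"{path}: {n_neg} dose voxel(s) are negative")
    return DoseGrid(grid=grid, dose=data)


def write_dose(dose: DoseGrid, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(dose.dose.astype(np.float32), dose.grid.affine())
    nib.save(img, os.fspath(path))


#: column order of the per-structure metrics report
METRICS_COLUMNS = (
    "structure",
    "volume_cm3",
    "ptv_overlap_cm3",
    "mean_eqd2_gy",
    "max_eqd2_gy",
)


def _sig_figs(value: float, digits: int = 6) -> str:
    """Format with a fixed count of significant figures, keeping trailing zeros."""
    return np.format_float_positional(
        float(value), precision=digits, unique=False, fractional=False, min_digits=digits
    ).rstrip(".")


def write_metrics_report(rows: Iterable[Mapping[str, object]], path: str | os.PathLike) -> None:
    """Write per-structure metrics as CSV: one header row, one row per structure.

    Each record must carry the keys in :data:`METRICS_COLUMNS`. Numbers are
    printed with 6 significant figures (trailing zeros kept).
    """
    rows = list(rows)
    for row in rows:
        missing = [c for c in METRICS_COLUMNS if c not in row]
        if missing:
            raise ValueError(f"metrics record missing fields {missing}: {dict(row)}")
    frame = pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
    for col in METRICS_COLUMNS[1:]:
        frame[col] = frame[col].map(_sig_figs)
    frame.to_csv(path, index=False)


def write_dvh_table(
    dose_axis: np.ndarray,
    curves: Mapping[str, np.ndarray],
    path: str | os.PathLike,
) -> None:
    """Write a DVH table: one dose-axis column, one %-volume column per structure."""
    frame = pd.DataFrame({"dose_gy": np.asarray(dose_axis, dtype=float)})
    for name, values in curves.items():
        values = np.asarray(values, dtype=float)
        if values.shape != frame["dose_gy"].shape:
            raise ValueError(f"curve {name!r} length {values.shape} != axis length")
        frame[name] = values
    frame.to_csv(path, index=False, float_format="%.6g")


def load_yaml_config(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg


def dump_yaml_config(config: Mapping[str, object], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
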