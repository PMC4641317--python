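"""Voxel-grid data model shared by structure masks and dose grids.

All geometry is expressed in world millimetres on axis-aligned regular grids:
x runs patient left-right, y anterior-posterior, z inferior-superior. Voxel
indices are 0-based and the centre of voxel (i, j, k) sits at
``origin + (i, j, k) * spacing``. A voxel belongs to a structure iff its
centre does — volumes are voxel counts times the voxel volume, with no
partial-volume weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "DoseGrid",
    "FractionationScheme",
    "GridMismatchError",
]

#: absolute tolerance (mm) for deciding two grids are the same frame
GRID_ATOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Raised when an operation requires two volumes on the same grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned regular voxel grid in world millimetres.

    Parameters
    ----------
    origin : (3,) array-like
        World coordinates (mm) of the centre of voxel (0, 0, 0).
    spacing : (3,) array-like
        Voxel pitch (mm) along each axis; all components strictly positive.
    dims : (3,) array-like of int
        Number of voxels along each axis; all components >= 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float).reshape(3))
        spacing = tuple(float(v) for v in np.asarray(self.spacing, dtype=float).reshape(3))
        dims = tuple(int(v) for v in np.asarray(self.dims).reshape(3))
        if any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise ValueError(f"spacing must be positive and finite, got {spacing}")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must all be >= 1, got {dims}")
        if any(not np.isfinite(o) for o in origin):
            raise ValueError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "dims", dims)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    def indices_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + ijk * np.asarray(self.spacing)

    def world_to_indices(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world coordinates (mm) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """4x4 index-to-world affine (diagonal; grids are axis-aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_frame_as(self, other: "VoxelGrid", atol: float = GRID_ATOL_MM) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )


def _require_same_frame(a: VoxelGrid, b: VoxelGrid, context: str) -> None:
    if not a.same_frame_as(b):
        raise GridMismatchError(
            f"{context}: volumes live on different grids "
            f"(dims {a.dims} vs {b.dims}, origin {a.origin} vs {b.origin}, "
            f"spacing {a.spacing} vs {b.spacing}); resample one onto the "
            "other's grid first (see resample_mask)."
        )


@dataclass
class StructureMask:
    """Named binary occupancy on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid dims {self.grid.dims}"
            )
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"occupancy must be strictly binary, found values {vals[:5]}"
                )
            occ = occ.astype(bool)
        self.occupancy = occ

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def volume_cm3(self) -> float:
        """Occupied-voxel count times voxel volume, in cm^3."""
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0

    def with_occupancy(self, occupancy: np.ndarray, name: str | None = None) -> "StructureMask":
        return StructureMask(name or self.name, self.grid, occupancy)


@dataclass
class DoseGrid:
    """Per-voxel total physical (or EQD2-converted) dose in Gy."""

    grid: VoxelGrid
    dose: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        if dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {dose.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.isfinite(dose).all():
            raise ValueError("dose values must all be finite")
        n_neg = int((dose < 0).sum())
        if n_neg:
            raise ValueError(f"dose values must be non-negative; {n_neg} voxel(s) are negative")
        self.dose = dose


@dataclass(frozen=True)
class FractionationScheme:
    """Fractionation of a delivered plan, for EQD2 conversion.

    ``alpha_beta`` is the linear-quadratic alpha/beta ratio in Gy; 10 Gy is
    the conventional value for acute-responding tissues such as mucosa. The
    reference dose per fraction is fixed at 2 Gy by the EQD2 definition.
    """

    n_fractions: int
    alpha_beta: float = 10.0
    reference_dose_per_fraction: float = 2.0

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        if not (self.alpha_beta > 0):
            raise ValueError(f"alpha_beta must be > 0 Gy, got {self.alpha_beta}")
        if self.reference_dose_per_fraction != 2.0:
            raise ValueError("EQD2 is defined at a reference dose of 2 Gy per fraction")
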