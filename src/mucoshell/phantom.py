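"""Seeded oral-cavity phantom: geometry, mucosal sheet and dose for testing.

The phantom stands in for one patient's planning CT, contours and plan. It is
built from analytic primitives so every geometric operation has a closed-form
oracle:

* the oral cavity (OCC analogue) is an ellipsoid (lateral, AP, SI semi-axes);
* the tongue is a smaller ellipsoid strictly inside it, offset inferiorly;
* the mucosal sheet is the one-voxel-thick inner boundary layer of the
  cavity, minus a posterior cap (the opening to the oropharynx, where there
  is no mucosal wall to delineate), plus the superior-facing boundary layer
  of the tongue (the dorsum);
* the ground-truth shell (MSC) is the 3 mm symmetric expansion of the sheet;
* the PTV is a sphere placed medially/posteriorly, overlapping the cavity;
* the dose is at prescription inside the PTV, falls off outside as a
  Gaussian of the distance to the PTV surface, and carries a mild
  multiplicative hotspot (a few percent, as IMRT plans show) centred on the
  tongue's core — the medial muscle bulk where overlapping beams
  concentrate — so the plan maximum sits in deep musculature, not on a
  mucosal surface. A minimal medially concentrated model, not a beam model.

Identical spec + seed give bit-identical volumes and dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ShellParams, expand_sheet_to_shell
from .grids import DoseGrid, FractionationScheme, StructureMask, VoxelGrid

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "generate_cohort"]

_Vec3 = tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic oral-cavity case. Lengths in mm, doses in Gy."""

    spacing: _Vec3 = (1.0, 1.0, 1.0)
    extent: _Vec3 = (120.0, 120.0, 100.0)
    cavity_semiaxes: _Vec3 = (35.0, 45.0, 30.0)
    tongue_semiaxes: _Vec3 = (25.0, 35.0, 18.0)
    tongue_offset: _Vec3 = (0.0, 0.0, -12.0)
    posterior_opening_halfangle_deg: float = 40.0
    ptv_center: _Vec3 = (0.0, 25.0, -5.0)
    ptv_radius: float = 25.0
    prescription_dose_gy: float = 65.0
    n_fractions: int = 30
    hotspot_fraction: float = 0.05
    hotspot_sigma_mm: float = 15.0
    falloff_sigma_mm: float = 10.0
    noise_sd_gy: float = 0.0
    shell_thickness_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spacing", "extent", "cavity_semiaxes", "tongue_semiaxes"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(not (v > 0) for v in vals):
                raise ValueError(f"{name} must be three positive lengths, got {vals}")
        if any(s > 2.0 for s in self.spacing):
            raise ValueError(
                f"spacing {self.spacing} too coarse: all components must be <= 2 mm "
                "so a 3 mm shell is resolvable"
            )
        for name in ("ptv_radius", "prescription_dose_gy", "falloff_sigma_mm",
                     "hotspot_sigma_mm", "shell_thickness_mm"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_sd_gy < 0 or self.hotspot_fraction < 0:
            raise ValueError("noise_sd_gy and hotspot_fraction must be >= 0")
        if not (0 <= self.posterior_opening_halfangle_deg < 90):
            raise ValueError("posterior_opening_halfangle_deg must be in [0, 90)")
        if not self._tongue_inside_cavity():
            raise ValueError(
                "tongue ellipsoid must lie inside the cavity ellipsoid "
                f"(tongue {self.tongue_semiaxes} at {self.tongue_offset} vs "
                f"cavity {self.cavity_semiaxes})"
            )

    def _tongue_inside_cavity(self, n_theta: int = 48, n_phi: int = 96) -> bool:
        # sample the tongue surface densely and require every point inside the
        # closed cavity ellipsoid; touching is allowed (with the default
        # anatomy the tongue's inferior pole rests on the floor of mouth,
        # i.e. exactly on the cavity boundary). The 1e-3 slack on the implicit
        # function tolerates sub-micrometre protrusion, far below voxel size;
        # the generated tongue occupancy is clipped to the cavity regardless.
        theta = np.linspace(0, np.pi, n_theta)
        phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
        T, P = np.meshgrid(theta, phi, indexing="ij")
        at, bt, ct = self.tongue_semiaxes
        ox, oy, oz = self.tongue_offset
        x = ox + at * np.sin(T) * np.cos(P)
        y = oy + bt * np.sin(T) * np.sin(P)
        z = oz + ct * np.cos(T)
        a, b, c = self.cavity_semiaxes
        return bool(((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0 + 1e-3).all())

    def grid(self) -> VoxelGrid:
        """Grid centred on the cavity: world origin at the phantom's centre."""
        dims = tuple(int(round(e / s)) for e, s in zip(self.extent, self.spacing))
        origin = tuple(-(d - 1) * s / 2.0 for d, s in zip(dims, self.spacing))
        return VoxelGrid(origin=origin, spacing=self.spacing, dims=dims)


@dataclass
class PhantomCase:
    """One synthetic patient: contours, ground-truth shell, PTV, dose, plan."""

    occ_solid: StructureMask
    mucosal_sheet: StructureMask
    msc_truth: StructureMask
    ptv: StructureMask
    dose: DoseGrid
    scheme: FractionationScheme
    spec: PhantomSpec = field(repr=False)


def _boundary_layer(solid: np.ndarray) -> np.ndarray:
    """One-voxel-thick inner boundary: voxels with a 6-neighbour outside."""
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(solid, structure=struct, border_value=0)
    return solid & ~eroded


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build the phantom deterministically from its spec (bit-identical per seed)."""
    grid = spec.grid()
    xs, ys, zs = grid.axis_coordinates()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    a, b, c = spec.cavity_semiaxes
    cavity = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    occ_solid = StructureMask("occ", grid, cavity)

    at, bt, ct = spec.tongue_semiaxes
    ox, oy, oz = spec.tongue_offset
    tongue = ((X - ox) / at) ** 2 + ((Y - oy) / bt) ** 2 + ((Z - oz) / ct) ** 2 <= 1.0
    tongue &= cavity  # guard against float fuzz where the tongue rests on the wall

    # cavity wall sheet, minus the posterior opening cap: exclude boundary
    # voxels whose normalised direction lies within the half-angle of +y
    cavity_boundary = _boundary_layer(cavity)
    u = np.stack([X / a, Y / b, Z / c])
    norm = np.sqrt((u**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_posterior = np.where(norm > 0, u[1] / np.where(norm > 0, norm, 1.0), 0.0)
    cap = cos_posterior >= np.cos(np.deg2rad(spec.posterior_opening_halfangle_deg))
    wall_sheet = cavity_boundary & ~cap

    # tongue dorsum: boundary voxels whose outward normal points superiorly
    tongue_boundary = _boundary_layer(tongue)
    dorsum = tongue_boundary & (Z > oz)

    sheet = StructureMask("mucosal_sheet", grid, wall_sheet | dorsum)
    msc = expand_sheet_to_shell(sheet, ShellParams(spec.shell_thickness_mm))
    msc.name = "msc"

    px, py, pz = spec.ptv_center
    r = np.sqrt((X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2)
    ptv = StructureMask("ptv", grid, r <= spec.ptv_radius)

    # dose: prescription inside the PTV with a mild in-PTV hotspot centred on
    # the tongue core (deep medial musculature, where overlapping beams
    # concentrate), Gaussian falloff of the distance to the PTV surface
    # outside. The hotspot factor is strictly > 1 inside the PTV, so the plan
    # maximum is the in-PTV voxel nearest the tongue centre.
    surface_dist = np.maximum(r - spec.ptv_radius, 0.0)
    falloff = np.exp(-(surface_dist**2) / (2.0 * spec.falloff_sigma_mm**2))
    r_tongue_sq = (X - ox) ** 2 + (Y - oy) ** 2 + (Z - oz) ** 2
    hotspot = 1.0 + spec.hotspot_fraction * np.exp(
        -r_tongue_sq / (2.0 * spec.hotspot_sigma_mm**2)
    )
    dose_vals = spec.prescription_dose_gy * falloff * np.where(
        r <= spec.ptv_radius, hotspot, 1.0
    )
    if spec.noise_sd_gy > 0:
        rng = np.random.default_rng(spec.seed)
        dose_vals = np.clip(
            dose_vals + rng.normal(0.0, spec.noise_sd_gy, size=dose_vals.shape), 0.0, None
        )

    return PhantomCase(
        occ_solid=occ_solid,
        mucosal_sheet=sheet,
        msc_truth=msc,
        ptv=ptv,
        dose=DoseGrid(grid, dose_vals),
        scheme=FractionationScheme(n_fractions=spec.n_fractions),
        spec=spec,
    )


#: per-patient jitter bounds used by generate_cohort
_SEMIAXIS_JITTER = 0.10      # +-10 % on cavity and tongue semi-axes
_PTV_CENTER_JITTER_MM = 8.0  # +-8 mm on each PTV-centre coordinate
_PTV_RADIUS_JITTER_MM = 5.0  # +-5 mm on the PTV radius
_MAX_REDRAWS = 25


def _jitter_spec(base: PhantomSpec, rng: np.random.Generator, case_seed: int) -> PhantomSpec:
    scale_cav = 1.0 + rng.uniform(-_SEMIAXIS_JITTER, _SEMIAXIS_JITTER, 3)
    scale_ton = 1.0 + rng.uniform(-_SEMIAXIS_JITTER, _SEMIAXIS_JITTER, 3)
    center = np.asarray(base.ptv_center) + rng.uniform(
        -_PTV_CENTER_JITTER_MM, _PTV_CENTER_JITTER_MM, 3
    )
    radius = base.ptv_radius + rng.uniform(-_PTV_RADIUS_JITTER_MM, _PTV_RADIUS_JITTER_MM)
    return replace(
        base,
        cavity_semiaxes=tuple(np.asarray(base.cavity_semiaxes) * scale_cav),
        tongue_semiaxes=tuple(np.asarray(base.tongue_semiaxes) * scale_ton),
        ptv_center=tuple(center),
        ptv_radius=float(radius),
        seed=case_seed,
    )


def generate_cohort(
    base: PhantomSpec, n_patients: int, seed: int
) -> list[PhantomCase]:
    """Seeded cohort of jittered phantoms (anatomy and PTV placement vary).

    A jittered spec that violates the phantom invariants (e.g. the tongue no
    longer strictly inside the cavity) is redrawn from the same stream, up to
    a bounded retry count. Same seed, same cohort.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n_patients):
        case_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(_MAX_REDRAWS):
            try:
                spec = _jitter_spec(base, rng, case_seed)
            except ValueError:
                continue
            cases.append(generate_phantom(spec))
            break
        else:
            raise RuntimeError(
                f"could not draw a valid jittered phantom for patient {i} "
                f"after {_MAX_REDRAWS} attempts"
            )
    return cases
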