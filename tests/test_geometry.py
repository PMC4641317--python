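"""Shell constructions checked against closed-form volumes of analytic solids."""

import numpy as np
import pytest

from mucoshell import (
    GridMismatchError,
    ShellParams,
    StructureMask,
    derive_occ_surface,
    expand_sheet_to_shell,
    overlap_volume,
    resample_mask,
    structure_volume,
)

from conftest import make_grid, sphere_mask


def flat_sheet(spacing, extent_xy=20.0, extent_z=10.0):
    """One-voxel sheet filling the central z-layer of a 20 x 20 mm grid."""
    dims = (
        int(round(extent_xy / spacing[0])),
        int(round(extent_xy / spacing[1])),
        int(round(extent_z / spacing[2])),
    )
    grid = make_grid(dims, spacing)
    occ = np.zeros(dims, bool)
    occ[:, :, dims[2] // 2] = True
    return StructureMask("sheet", grid, occ)


class TestExpandSheetToShell:
    def test_flat_sheet_slab_volume(self):
        # At h = 0.2 mm the digital slab is exactly 15 layers of 0.2 mm = 3 mm;
        # at h = 0.5 the inclusive-tie rule necessarily adds a full layer on
        # each side (7 x 0.5 = 3.5 mm), a frozen digitisation fact.
        shell = expand_sheet_to_shell(flat_sheet((0.5, 0.5, 0.2)), ShellParams(3.0))
        vol_mm3 = structure_volume(shell) * 1000
        assert vol_mm3 == pytest.approx(20 * 20 * 3, rel=0.05)

        coarse = expand_sheet_to_shell(flat_sheet((0.5, 0.5, 0.5)), ShellParams(3.0))
        assert structure_volume(coarse) * 1000 == pytest.approx(1400.0)

    def test_single_voxel_digital_ball(self):
        # thickness 3 -> ball of radius 1.5 mm around the voxel centre.
        # At 1 mm the digital ball is exactly the 19 lattice points with
        # norm <= 1.5; at 0.25 mm it approaches (4/3) pi 1.5^3 = 14.137 mm^3.
        for spacing, check in [
            (1.0, lambda v: v == pytest.approx(19.0)),
            (0.25, lambda v: v == pytest.approx(4 / 3 * np.pi * 1.5**3, rel=0.05)),
        ]:
            dims = tuple(int(round(9 / spacing)) for _ in range(3))
            grid = make_grid(dims, (spacing,) * 3)
            occ = np.zeros(dims, bool)
            occ[dims[0] // 2, dims[1] // 2, dims[2] // 2] = True
            shell = expand_sheet_to_shell(
                StructureMask("pt", grid, occ), ShellParams(3.0)
            )
            assert check(structure_volume(shell) * 1000)

    def test_result_superset_of_sheet(self):
        sheet = flat_sheet((1.0, 1.0, 1.0))
        shell = expand_sheet_to_shell(sheet, ShellParams(3.0))
        assert (shell.occupancy | sheet.occupancy == shell.occupancy).all()

    def test_monotone_in_thickness(self):
        sheet = flat_sheet((1.0, 1.0, 1.0))
        thin = expand_sheet_to_shell(sheet, ShellParams(2.0))
        thick = expand_sheet_to_shell(sheet, ShellParams(4.0))
        assert (thin.occupancy & ~thick.occupancy).sum() == 0
        assert thick.n_voxels > thin.n_voxels

    def test_anisotropic_distances_in_mm(self):
        # with 2 mm z-spacing, a 3 mm total wall reaches the adjacent z-layers
        # only if distance is computed in mm (1 vs 2 voxels is irrelevant)
        sheet = flat_sheet((0.5, 0.5, 2.0), extent_z=20.0)
        shell = expand_sheet_to_shell(sheet, ShellParams(3.0))
        layers = np.unique(np.argwhere(shell.occupancy)[:, 2])
        assert layers.size == 1  # 2 mm neighbours are 2 mm > 1.5 mm away

    def test_empty_sheet_rejected(self, small_grid):
        empty = StructureMask("none", small_grid, np.zeros(small_grid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            expand_sheet_to_shell(empty, ShellParams(3.0))

    def test_unresolvable_thickness_warns(self):
        sheet = flat_sheet((2.0, 2.0, 2.0))
        with pytest.warns(UserWarning, match="discontinuous"):
            expand_sheet_to_shell(sheet, ShellParams(1.0))

    def test_one_sided_expansion(self):
        sheet = flat_sheet((0.5, 0.5, 0.2))
        dims = sheet.grid.shape
        below = np.zeros(dims, bool)
        below[:, :, : dims[2] // 2] = True
        side = StructureMask("below", sheet.grid, below)
        one_sided = expand_sheet_to_shell(
            sheet, ShellParams(3.0), symmetric=False, restrict_to=side
        )
        # full 3 mm wall on one side of the line only
        assert structure_volume(one_sided) * 1000 == pytest.approx(1200, rel=0.08)
        zs = np.unique(np.argwhere(one_sided.occupancy)[:, 2])
        assert zs.max() == dims[2] // 2  # nothing above the sheet


class TestDeriveOccSurface:
    def test_sphere_annulus_analytic_volume(self):
        grid = make_grid((140, 140, 140), (0.5, 0.5, 0.5))
        solid = sphere_mask(grid, 30.0)
        surface = derive_occ_surface(solid, ShellParams(3.0))
        expected = 4 / 3 * np.pi * (30**3 - 27**3)
        assert structure_volume(surface) * 1000 == pytest.approx(expected, rel=0.03)

    def test_result_subset_and_volume_bound(self):
        grid = make_grid((80, 80, 80), (1.0, 1.0, 1.0))
        solid = sphere_mask(grid, 30.0)
        surface = derive_occ_surface(solid, ShellParams(3.0))
        assert (surface.occupancy & ~solid.occupancy).sum() == 0
        assert structure_volume(surface) < structure_volume(solid)

    def test_thin_solid_fully_kept(self):
        # a 2 mm slab eroded by 3 mm empties, so the annulus is the whole solid
        grid = make_grid((20, 20, 20), (0.5, 0.5, 0.5))
        occ = np.zeros(grid.shape, bool)
        occ[:, :, 8:12] = True  # 2 mm thick
        solid = StructureMask("slab", grid, occ)
        surface = derive_occ_surface(solid, ShellParams(3.0))
        assert np.array_equal(surface.occupancy, solid.occupancy)

    def test_thickness_equal_radius_keeps_whole_sphere(self):
        grid = make_grid((50, 50, 50), (0.5, 0.5, 0.5))
        solid = sphere_mask(grid, 10.0)
        surface = derive_occ_surface(solid, ShellParams(10.0))
        assert np.array_equal(surface.occupancy, solid.occupancy)

    def test_solid_touching_grid_edge_gets_surface(self):
        # exterior includes the region beyond the grid bounding box
        grid = make_grid((20, 20, 20), (1.0, 1.0, 1.0))
        solid = StructureMask("all", grid, np.ones(grid.shape, bool))
        surface = derive_occ_surface(solid, ShellParams(3.0))
        assert 0 < surface.n_voxels < solid.n_voxels
        assert surface.occupancy[0, 0, 0]  # corner voxel is near the exterior
        assert not surface.occupancy[10, 10, 10]

    def test_monotone_in_thickness(self):
        grid = make_grid((60, 60, 60), (1.0, 1.0, 1.0))
        solid = sphere_mask(grid, 25.0)
        s2 = derive_occ_surface(solid, ShellParams(2.0))
        s5 = derive_occ_surface(solid, ShellParams(5.0))
        assert (s2.occupancy & ~s5.occupancy).sum() == 0

    def test_empty_solid_rejected(self, small_grid):
        empty = StructureMask("none", small_grid, np.zeros(small_grid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            derive_occ_surface(empty, ShellParams(3.0))

    def test_resolution_convergence(self):
        # volumes at h and h/2 agree within 5% and approach the closed form
        expected = 4 / 3 * np.pi * (30**3 - 27**3)
        vols = {}
        for h in (1.0, 0.5):
            grid = make_grid((int(70 / h),) * 3, (h,) * 3)
            surface = derive_occ_surface(sphere_mask(grid, 30.0), ShellParams(3.0))
            vols[h] = structure_volume(surface) * 1000
        assert abs(vols[1.0] - vols[0.5]) / vols[0.5] < 0.05
        assert abs(vols[0.5] - expected) / expected < abs(vols[1.0] - expected) / expected + 0.02


class TestVolumesAndOverlap:
    def test_volume_count_times_voxel(self):
        grid = make_grid((10, 10, 10))
        mask = StructureMask("m", grid, np.ones(grid.shape, bool))
        assert structure_volume(mask) == pytest.approx(1.0)

    def test_empty_volume_zero(self, small_grid):
        mask = StructureMask("m", small_grid, np.zeros(small_grid.shape, bool))
        assert structure_volume(mask) == 0.0

    def test_anisotropic_voxel_volume(self):
        grid = make_grid((10, 10, 10), (1.0, 1.0, 2.0))
        mask = StructureMask("m", grid, np.ones(grid.shape, bool))
        assert structure_volume(mask) == pytest.approx(2.0)

    def test_disjoint_overlap_zero(self, small_grid):
        a = np.zeros(small_grid.shape, bool)
        b = np.zeros(small_grid.shape, bool)
        a[:3], b[7:] = True, True
        assert overlap_volume(
            StructureMask("a", small_grid, a), StructureMask("b", small_grid, b)
        ) == 0.0

    def test_nested_overlap_is_smaller_volume(self, small_grid):
        a = np.zeros(small_grid.shape, bool)
        a[4:6, 4:6, 4:6] = True
        b = np.ones(small_grid.shape, bool)
        ma, mb = StructureMask("a", small_grid, a), StructureMask("b", small_grid, b)
        assert overlap_volume(ma, mb) == pytest.approx(structure_volume(ma))
        assert overlap_volume(ma, mb) == overlap_volume(mb, ma)

    def test_nested_spheres_analytic(self):
        grid = make_grid((140, 140, 140), (0.5, 0.5, 0.5))
        inner = sphere_mask(grid, 10.0)
        outer = sphere_mask(grid, 30.0)
        expected = 4 / 3 * np.pi * 10**3
        assert overlap_volume(inner, outer) * 1000 == pytest.approx(expected, rel=0.03)

    def test_grid_mismatch_instructs_resampling(self):
        a = StructureMask("a", make_grid((5, 5, 5)), np.ones((5, 5, 5), bool))
        b = StructureMask("b", make_grid((6, 6, 6)), np.ones((6, 6, 6), bool))
        with pytest.raises(GridMismatchError, match="resample"):
            overlap_volume(a, b)


class TestResampleMask:
    def test_identity_on_same_grid(self, small_grid):
        rng = np.random.default_rng(0)
        mask = StructureMask("m", small_grid, rng.random(small_grid.shape) > 0.5)
        out = resample_mask(mask, small_grid)
        assert np.array_equal(out.occupancy, mask.occupancy)

    def test_downsampling_roughly_conserves_volume(self):
        fine = make_grid((60, 60, 60), (1.0, 1.0, 1.0))
        coarse = make_grid((30, 30, 30), (2.0, 2.0, 2.0))
        mask = sphere_mask(fine, 25.0)
        out = resample_mask(mask, coarse)
        assert structure_volume(out) == pytest.approx(structure_volume(mask), rel=0.10)

    def test_disjoint_target_is_empty(self, small_grid):
        mask = StructureMask("m", small_grid, np.ones(small_grid.shape, bool))
        far = make_grid((5, 5, 5), origin=(100.0, 100.0, 100.0))
        assert resample_mask(mask, far).is_empty
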