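import numpy as np
import pytest

from mucoshell import PhantomSpec, StructureMask, VoxelGrid, generate_phantom


def make_grid(dims, spacing=(1.0, 1.0, 1.0), origin=None):
    """Grid whose voxel centres are symmetric about the world origin by default."""
    if origin is None:
        origin = tuple(-(d - 1) * s / 2.0 for d, s in zip(dims, spacing))
    return VoxelGrid(origin=origin, spacing=spacing, dims=dims)


def sphere_mask(grid, radius, center=(0.0, 0.0, 0.0), name="sphere"):
    xs, ys, zs = grid.axis_coordinates()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    occ = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2
    return StructureMask(name, grid, occ)


@pytest.fixture(scope="session")
def default_case():
    """Default 1 mm phantom, shared read-only across tests."""
    return generate_phantom(PhantomSpec())


@pytest.fixture
def small_grid():
    return make_grid((10, 10, 10))
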