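import numpy as np
import pytest

from biodisperse.stack_metrics import VoxelStack


def random_stack(seed: int, shape=(10, 20, 20), p: float = 0.3,
                 dx: float = 1.0, dy: float = 1.0, dz: float = 1.0) -> VoxelStack:
    rng = np.random.default_rng(seed)
    return VoxelStack(rng.random(shape) < p, dx=dx, dy=dy, dz=dz)


def brute_biovolume(vs: VoxelStack) -> float:
    count = 0
    nz, ny, nx = vs.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if vs.mask[z, y, x]:
                    count += 1
    return count * vs.dx * vs.dy * vs.dz


def brute_surface_area(vs: VoxelStack) -> float:
    """Six-neighbor face scan with the package's boundary conventions:

    substratum (z=-1) and lateral out-of-bounds neighbors count as occupied
    (no exposed face); the open top (z=nz) counts as unoccupied (exposed).
    """
    nz, ny, nx = vs.shape
    m = vs.mask
    area = 0.0
    faces = {(1, 0, 0): vs.dy * vs.dz, (-1, 0, 0): vs.dy * vs.dz,
             (0, 1, 0): vs.dx * vs.dz, (0, -1, 0): vs.dx * vs.dz,
             (0, 0, 1): vs.dx * vs.dy, (0, 0, -1): vs.dx * vs.dy}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not m[z, y, x]:
                    continue
                for (dxi, dyi, dzi), a in faces.items():
                    xx, yy, zz = x + dxi, y + dyi, z + dzi
                    if zz == nz:
                        area += a  # open top is exposed
                    elif zz < 0 or xx < 0 or xx >= nx or yy < 0 or yy >= ny:
                        continue  # substratum and lateral boundary: unexposed
                    elif not m[zz, yy, xx]:
                        area += a
    return area


def brute_thickness(vs: VoxelStack) -> np.ndarray:
    nz, ny, nx = vs.shape
    L = np.zeros((ny, nx))
    for y in range(ny):
        for x in range(nx):
            for z in range(nz - 1, -1, -1):
                if vs.mask[z, y, x]:
                    L[y, x] = (z + 1) * vs.dz
                    break
    return L


@pytest.fixture
def slab():
    """Solid 8x8x10 slab with unit voxels."""
    return VoxelStack(np.ones((10, 8, 8), dtype=bool))
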