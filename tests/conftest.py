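import numpy as np
import pytest

from thalnet.io_core import Mask, Volume
from thalnet.phantom import PhantomConfig, build_phantom
from thalnet.tracking import OrientationField


def make_grid(n: int = 20, voxel: float = 1.0) -> Volume:
    """Centered isotropic grid for hand-built scenes."""
    aff = np.eye(4)
    aff[:3, :3] *= voxel
    aff[:3, 3] = -(n - 1) / 2 * voxel
    return Volume(np.zeros((n, n, n)), aff)


def straight_field(
    n: int = 20,
    voxel: float = 1.0,
    axis: int = 0,
    amplitude: float = 1.0,
    background: float = 0.05,
    tube_radius_vox: float | None = None,
) -> OrientationField:
    """Single-lobe field along one axis; optionally confined to a tube around
    the grid's central line with sub-cutoff background elsewhere."""
    dirs = np.zeros((n, n, n, 1, 3))
    amps = np.full((n, n, n, 1), background)
    d = np.zeros(3)
    d[axis] = 1.0
    dirs[..., 0, :] = d
    if tube_radius_vox is None:
        amps[..., 0] = amplitude
    else:
        idx = np.indices((n, n, n)).transpose(1, 2, 3, 0).astype(float)
        center = (n - 1) / 2
        perp = [i for i in range(3) if i != axis]
        r = np.sqrt(sum((idx[..., i] - center) ** 2 for i in perp))
        amps[..., 0] = np.where(r <= tube_radius_vox, amplitude, background)
    grid = make_grid(n, voxel)
    return OrientationField(dirs, amps, grid.affine)


def slab_mask(grid: Volume, axis: int, lo: int, hi: int) -> Mask:
    values = np.zeros(grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, hi)
    values[tuple(sl)] = True
    return Mask(values, grid.affine)


@pytest.fixture(scope="session")
def phantom_cfg() -> PhantomConfig:
    return PhantomConfig(cohort_size=12, seed=11)


@pytest.fixture(scope="session")
def phantom0(phantom_cfg):
    return build_phantom(phantom_cfg, 0)
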