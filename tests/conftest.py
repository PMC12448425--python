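import numpy as np
import pytest

from gliomashape.mask_io import VolumeGrid, validate_pair
from gliomashape.synthetic_data import PhantomSpec, make_phantom


def ball_grid(radius, spacing=1.0, margin=3.0, label="tumor"):
    """Voxelize a centered ball by voxel-center membership."""
    n_half = int(np.ceil((radius + margin) / spacing))
    ax = np.arange(-n_half, n_half + 1) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = x**2 + y**2 + z**2 <= radius**2
    return VolumeGrid.from_array(data, (spacing,) * 3, (float(ax[0]),) * 3, label=label)


def block_grid(shape, block, spacing=(1.0, 1.0, 1.0), offset=(0, 0, 0), label="tumor"):
    """A rectangular block of foreground inside an all-zero lattice."""
    data = np.zeros(shape, dtype=np.uint8)
    sl = tuple(slice(o, o + b) for o, b in zip(offset, block))
    data[sl] = 1
    return VolumeGrid.from_array(data, spacing, label=label)


@pytest.fixture(scope="session")
def interior_pair():
    """Tumor block strictly interior to a larger brain block."""
    tumor = block_grid((20, 20, 20), (5, 5, 5), offset=(8, 8, 8))
    brain = block_grid((20, 20, 20), (16, 16, 16), offset=(2, 2, 2), label="brain")
    return validate_pair(tumor, brain)


@pytest.fixture(scope="session")
def ball_pair_1mm():
    """Interior ball phantom, r = 20 mm at 1 mm spacing, with oracle."""
    return make_phantom(PhantomSpec(family="ball", radius=20.0, spacing=1.0))


@pytest.fixture(scope="session")
def clipped_pair_05mm():
    """Plane-clipped ball, r = 10 mm, depth 5 mm, 0.5 mm spacing."""
    return make_phantom(
        PhantomSpec(family="clipped_ball", radius=10.0, clip_depth=5.0, spacing=0.5)
    )
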