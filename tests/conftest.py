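import numpy as np
import pytest

from cartiq import CartilageMask, Grid, PhantomSpec, generate_phantom


def make_slab_mask(
    k: int = 10,
    pixel_size: float = 0.365,
    n_cols: int = 20,
    pad_above: int = 4,
    bone_rows: int = 4,
    n_slices: int = 1,
    region: int = 2,
) -> CartilageMask:
    """Full-width cartilage slab of ``k`` voxel rows: background above,
    bone below; lateral edges touch the volume edge (neither boundary)."""
    n_rows = pad_above + k + bone_rows
    labels = np.zeros((n_slices, n_rows, n_cols), dtype=np.int16)
    labels[:, pad_above : pad_above + k, :] = region
    labels[:, pad_above + k :, :] = 1
    return CartilageMask(labels, Grid(pixel_size, 3.0))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small annular-arc phantom without noise, with its ground truth."""
    spec = PhantomSpec(shape=(3, 56, 56), sigma=0.0)
    series, mask, truth = generate_phantom(spec, seed=11)
    return spec, series, mask, truth


@pytest.fixture
def slab_mask():
    return make_slab_mask
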