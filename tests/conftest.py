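import warnings

import numpy as np
import pytest

from srslipid.io_stacks import RamanChannelStack, VoxelGeometry
from srslipid.phantom import PhantomSpec

warnings.filterwarnings("ignore", category=FutureWarning)

DEFAULT_GEOMETRY = VoxelGeometry(0.3, 0.3, 1.0)


@pytest.fixture
def geometry() -> VoxelGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A light phantom for unit tests (full-size runs live in acceptance)."""
    return PhantomSpec(
        grid_shape=(24, 100, 100),
        geometry=DEFAULT_GEOMETRY,
        cells=(((15.0, 15.0, 12.0), 11.0),),
        droplets_per_cell=12,
        seed=42,
    )


def make_stack(array, wavenumber=2900.0, geometry=DEFAULT_GEOMETRY) -> RamanChannelStack:
    return RamanChannelStack(np.asarray(array, dtype=float), wavenumber, geometry)


def match_to_truth(droplets, truth_droplets, max_dist_um=2.0):
    """Pair measured droplets with ground-truth rows by centroid proximity.

    Returns (pairs, unmatched_droplets) where each pair is
    (droplet, truth_row_index).
    """
    pairs, unmatched = [], []
    for d in droplets:
        d2 = (
            (truth_droplets.x_um - d.centroid[0]) ** 2
            + (truth_droplets.y_um - d.centroid[1]) ** 2
            + (truth_droplets.z_um - d.centroid[2]) ** 2
        )
        i = int(np.argmin(d2))
        if d2[i] < max_dist_um**2:
            pairs.append((d, i))
        else:
            unmatched.append(d)
    return pairs, unmatched
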