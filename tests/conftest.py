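import numpy as np
import pytest

from fibrest import (PhantomSpec, ScaleParams, analyse_volume,
                     build_parallel_fibre_volume)


@pytest.fixture(scope="session")
def parallel_small():
    """48³ noiseless parallel phantom at 1 μm voxels, fibres along +x."""
    spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0, rng_seed=1)
    vol, truth = build_parallel_fibre_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def parallel_small_eigen(parallel_small):
    """Structure-tensor eigen field of the small parallel phantom."""
    _, vol, _ = parallel_small
    eigen, dom = analyse_volume(vol, ScaleParams(scales=((1.0, 3.0),),
                                                 gamma=0.3))
    return eigen, dom


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
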