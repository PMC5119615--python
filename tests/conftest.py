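import numpy as np
import pytest

from specdot import phantoms
from specdot.meshing import box_volume, volume_to_mesh
from specdot.spectra import OpticalProps


@pytest.fixture(scope="session")
def small_slab_mesh():
    """16 x 16 x 12 mm slab at 2 mm voxels: fine enough for positive fluence."""
    return volume_to_mesh(box_volume((16.0, 16.0, 12.0), 2.0))


@pytest.fixture(scope="session")
def small_slab_optodes(small_slab_mesh):
    return phantoms.single_view_optodes(
        small_slab_mesh, n_sources=(2, 2), source_spacing=6.0,
        n_detectors=(3, 3), detector_spacing=4.0, n_omitted_sources=0)


@pytest.fixture(scope="session")
def homogeneous_props(small_slab_mesh):
    n = small_slab_mesh.n_nodes
    return OpticalProps(mua=np.full(n, 0.01), musp=np.full(n, 1.0))


@pytest.fixture(scope="session")
def coarse_block():
    """4 mm block phantom for fast calibration/pipeline tests."""
    return phantoms.build_block_phantom(resolution=4.0)


@pytest.fixture(scope="session")
def coarse_block_optodes(coarse_block):
    return phantoms.single_view_optodes(coarse_block.mesh)
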