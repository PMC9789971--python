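import numpy as np
import pytest

from disconnectomics import Parcellation, make_parcellation, make_tractogram


@pytest.fixture(scope="session")
def toy_parcellation() -> Parcellation:
    """Small deterministic parcellation: 6 right + 4 left ROIs, 2 mm voxels."""
    return make_parcellation(6, 4, voxel_size_mm=2.0, seed=1)


@pytest.fixture(scope="session")
def toy_bundles(toy_parcellation):
    """A fixed bundle specification and its zero-wobble tractogram."""
    spec = {(1, 2): 5, (1, 3): 3, (2, 8): 4, (4, 5): 6}
    streamlines = make_tractogram(toy_parcellation, spec, wobble_sd_mm=0.0, seed=3)
    return spec, streamlines


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
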