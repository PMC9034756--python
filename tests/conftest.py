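import numpy as np
import pytest

from histoslice_quant import (
    SlicePlane,
    make_synthetic_slice,
    make_toy_atlas,
    make_true_transform,
)

#: toy volume used across tests: big enough that four nested regions all
#: keep interior pixels >= 3 voxels from their in-plane borders
TOY_SHAPE = (60, 100, 140)
TOY_CANVAS = (100, 140)
CELLS_PER_REGION = {1: 60, 2: 60, 3: 40, 4: 40}


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy_atlas(seed=1, shape=TOY_SHAPE, n_regions=4, variant="allen")


@pytest.fixture(scope="session")
def chon_bundle():
    return make_toy_atlas(seed=1, shape=TOY_SHAPE, n_regions=4, variant="chon")


@pytest.fixture(scope="session")
def center_plane():
    return SlicePlane(plane="coronal", position_mm=0.0)


@pytest.fixture(scope="session")
def fixture_truth(toy_bundle, center_plane, tmp_path_factory):
    """One rendered synthetic slice (200 cells, known truth) shared per session."""
    transform = make_true_transform(seed=11, canvas_shape=TOY_CANVAS)
    return make_synthetic_slice(
        toy_bundle,
        center_plane,
        true_transform=transform,
        cells_per_region=CELLS_PER_REGION,
        pixel_size_um=0.5,
        seed=7,
        canvas_shape=TOY_CANVAS,
        out_dir=tmp_path_factory.mktemp("fixture_slice"),
        slice_id="slice_fix",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
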