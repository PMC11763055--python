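import numpy as np
import pytest

from avsmotion import DatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dl_pairs():
    """24 DL pairs on the full 32x32 grid (3 per direction, size 16)."""
    spec = DatasetSpec(configurations=("DL",), object_sizes=(16,),
                       pairs_per_direction=3, seed=7)
    pairs, manifest = generate_dataset(spec)
    return pairs, manifest


@pytest.fixture(scope="session")
def tiny_8x8_pairs():
    """Random-config pairs on an 8x8 grid for cheap exhaustive checks."""
    spec = DatasetSpec(image_height=8, image_width=8,
                       configurations=("DL", "RD"), object_sizes=(4,),
                       pairs_per_direction=1, seed=3)
    pairs, _ = generate_dataset(spec)
    return pairs
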