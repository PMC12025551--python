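import numpy as np
import pytest

from fractalseg.metrics import BinaryMask
from fractalseg.phantom import PhantomParams, generate_dataset


def mask(rows, spacing=(1.0, 1.0)) -> BinaryMask:
    """Build a BinaryMask from a list of strings ('.'=0, '#'=1)."""
    grid = np.array([[1 if ch == "#" else 0 for ch in row] for row in rows], dtype=np.uint8)
    return BinaryMask(grid, spacing)


@pytest.fixture(scope="session")
def small_phantom_params() -> PhantomParams:
    """64x64 phantom geometry used throughout the training tests."""
    return PhantomParams(image_size=(64, 64), seed=11, center_jitter_px=4)


@pytest.fixture(scope="session")
def phantom_pairs(small_phantom_params):
    pairs, _ = generate_dataset(small_phantom_params, n=160)
    return pairs
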