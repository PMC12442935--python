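"""Shared synthetic fixtures (session-scoped: rendering is the slow part)."""

import numpy as np
import pytest

from endovia import synthetic
from endovia.raster import BinaryMask, RasterImage


@pytest.fixture(scope="session")
def clean_fixture():
    """Clean-preset fixture with ~12% planted mortality."""
    return synthetic.generate_fixture(
        synthetic.preset_spec("clean", seed=11, target_mortality=0.12)
    )


@pytest.fixture(scope="session")
def blank_fixture():
    """Clean-preset fixture with no planted stains."""
    return synthetic.generate_fixture(
        synthetic.preset_spec("clean", seed=5, target_mortality=0.0)
    )


@pytest.fixture(scope="session")
def standard_fixture():
    return synthetic.generate_fixture(
        synthetic.preset_spec("standard", seed=21, target_mortality=0.15)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape, p=0.3) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p)


def dice_of(pred: BinaryMask, truth: BinaryMask) -> float:
    inter = (pred.membership & truth.membership).sum()
    denom = pred.area + truth.area
    return 1.0 if denom == 0 else 2 * inter / denom


@pytest.fixture()
def gray_image(rng) -> RasterImage:
    return RasterImage(rng.integers(0, 256, (40, 40), dtype=np.uint8))
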