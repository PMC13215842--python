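import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cytofuse.synthgen import ClassRecipe, default_recipes, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny4():
    """Small 4-class dataset (64 px) used by most unit tests."""
    return generate_dataset(default_recipes((6, 8, 10, 12), image_size=64), rng=7)


@pytest.fixture(scope="session")
def gray_image():
    """A mid-gray 128 x 128 image record for noise-statistics tests."""
    from cytofuse.datatypes import ImageRecord

    return ImageRecord(
        pixels=np.full((128, 128, 3), 128, dtype=np.uint8), label="gray"
    )


def single_ellipse_recipe(radius=10.0, ecc=0.0, size=64, **kw):
    return ClassRecipe(
        name="one",
        n_images=1,
        cell_radius_range=(radius, radius),
        eccentricity_range=(ecc, ecc),
        image_size=size,
        **kw,
    )
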