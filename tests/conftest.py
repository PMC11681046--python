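import numpy as np
import pytest

from spheroquant import (
    Annulus,
    BinaryMask,
    Disk,
    FixtureSpec,
    SinglePixels,
    generate_pair,
)


@pytest.fixture(scope="session")
def annulus_fixture():
    """Disk r0=50 plus annulus invasion 50 < r <= 60, 1 um/px."""
    spec = FixtureSpec(
        image_shape=(161, 161),
        pixel_size_um=1.0,
        spheroid=Disk(50.0),
        invasion=Annulus(50.0, 60.0),
    )
    day0, day2, truth = generate_pair(spec)
    return day0, day2, truth


@pytest.fixture(scope="session")
def single_pixel_fixture():
    """Disk r0=50 with one invading pixel at radius 80 (odd frame: exact center)."""
    spec = FixtureSpec(
        image_shape=(201, 201),
        pixel_size_um=1.0,
        spheroid=Disk(50.0),
        invasion=SinglePixels([(80.0, 0.0)]),
    )
    day0, day2, truth = generate_pair(spec)
    return day0, day2, truth


@pytest.fixture
def disk_mask():
    """Plain rasterized disk mask, radius 50, centered on a 161x161 frame."""
    spec = FixtureSpec(image_shape=(161, 161), spheroid=Disk(50.0))
    day0, _, _ = generate_pair(spec)
    return day0


def make_mask(pixels, pixel_size_um=1.0, **kw) -> BinaryMask:
    return BinaryMask(np.asarray(pixels, dtype=bool), pixel_size_um, **kw)
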