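import numpy as np
import pytest

from csjnd import fixtures, image_io


@pytest.fixture
def rng():
    return np.random.default_rng(20230227)


@pytest.fixture(scope="session")
def suite():
    """The canonical 12-stimulus regression set."""
    return fixtures.fixture_suite()


def make_ycbcr(spec: fixtures.FixtureSpec):
    """Generate a fixture and return (rgb, ycbcr)."""
    rgb = fixtures.generate(spec)
    return rgb, image_io.rgb_to_ycbcr(rgb)


@pytest.fixture(scope="session")
def random_rgb():
    """Seeded 32x32 random color image as an RGBImage."""
    gen = np.random.default_rng(42)
    return image_io.RGBImage.from_array(
        gen.integers(0, 256, size=(32, 32, 3)).astype(float)
    )
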