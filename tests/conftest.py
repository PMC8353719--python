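import numpy as np
import pytest

from tmipack import fixtures as fx


@pytest.fixture(scope="session")
def worked_example():
    """945x1327 8-bit image with exactly 5963 pixels at gradation 125."""
    return fx.worked_example_image()


@pytest.fixture()
def small_random_image():
    return fx.random_image(20, 20, 256, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
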