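import numpy as np
import pytest

from ctnoise import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def white_phantom():
    """Mid-size white-noise phantom (sigma = 10 HU) with ground truth."""
    spec = PhantomSpec(
        shape=(6, 256, 256),
        pixel_spacing_mm=1.0,
        body_semi_axes_mm=(80.0, 100.0),
        sigma_hu=10.0,
        seed=42,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(
        shape=(4, 128, 128),
        pixel_spacing_mm=1.0,
        body_semi_axes_mm=(40.0, 50.0),
        sigma_hu=0.0,
        seed=0,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
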