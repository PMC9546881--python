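import numpy as np
import pytest

from casabench import psf


@pytest.fixture(scope="session")
def appearance():
    return psf.AppearanceParams()


@pytest.fixture(scope="session")
def kernels(appearance):
    hw = appearance.kernel_half_width
    return {
        "f1": psf.make_gaussian_psf(appearance.sigma_head, hw),
        "f2": psf.make_halo_psf(appearance.sigma_membrane, hw),
        "f3": psf.make_ridge_psf(appearance.sigma_flagellum, hw),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
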