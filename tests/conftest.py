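import numpy as np
import pytest

from patchadapt.params import Patch, PatchLayout, PopulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def base_params():
    """A well-behaved 1D parameter set inside the theory's validity region."""
    return PopulationParams(
        sigma=1.0, s_m=0.05, s_p=0.1, mu=1e-5, rho=10.0, xi2=1.0, C=1.0, d=1
    )


@pytest.fixture
def two_patch_layout():
    patch = Patch(area=10.0, w_lin=10.0)
    return PatchLayout(
        patches=(patch, patch),
        distances=np.array([[0.0, 30.0], [30.0, 0.0]]),
    )
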