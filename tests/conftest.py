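import numpy as np
import pytest

from pulsecr import HarmonicPRC, ModelParams, ml_like_prc


@pytest.fixture(scope="session")
def harmonic_params():
    """The reference ensemble: N=240, omega=1, kappa=0.5, Z = -sin."""
    return ModelParams(240, 1.0, 0.5, HarmonicPRC())


@pytest.fixture(scope="session")
def ml_params():
    """Same ensemble with the synthetic Morris-Lecar-like tabulated PRC."""
    return ModelParams(240, 1.0, 0.5, ml_like_prc())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
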