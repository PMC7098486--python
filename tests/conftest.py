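import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def candidates():
    from ubquant.chem import ub_dgg_candidates

    return ub_dgg_candidates()


@pytest.fixture(scope="session")
def noise_free_sim():
    """Small noise-free simulation parameters shared across intact tests."""
    from ubquant.simulate import SpectrumSimParams

    return SpectrumSimParams(noise_level=0.0, n_scans=3, seed=11)


@pytest.fixture(scope="session")
def deconv_params():
    from ubquant.intact import DeconvParams, UB_MASS_RANGE

    return DeconvParams(mass_range=UB_MASS_RANGE)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
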