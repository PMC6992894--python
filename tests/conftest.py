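import pytest
from hypothesis import settings

from crpen import PenetrationParams, SyntheticSpec, generate_series

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def standard_params() -> PenetrationParams:
    """Published parameters of the homogeneous FITC standard sample."""
    return PenetrationParams(D=0.138, K=2.233)


@pytest.fixture(scope="session")
def hm20_params() -> PenetrationParams:
    """Published parameters of the HM20 resin-embedded GFP brain sample."""
    return PenetrationParams(D=0.026, K=1.404)


@pytest.fixture(scope="session")
def noiseless_series(standard_params):
    """Small noise-free homogeneous series for exact round-trip checks."""
    spec = SyntheticSpec(
        params=standard_params, nx=8, ny=8, gaussian_sigma=0.0, seed=11
    )
    series, _ = generate_series(spec)
    return series
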