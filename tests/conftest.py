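import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def one_comp():
    """Avibactam-like 1-compartment parameters: CL 12 L/h, t1/2 2.5 h."""
    from crosspk import PkParameters

    return PkParameters(clearance=12.0, central_volume=12.0 * 2.5 / np.log(2.0))


@pytest.fixture
def two_comp():
    from crosspk import PkParameters

    return PkParameters(
        clearance=7.0,
        central_volume=12.0,
        peripheral_volume=10.0,
        intercompartmental_clearance=8.0,
    )
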