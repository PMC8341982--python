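import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_chain():
    """Full parameter set derived once from the bundled measurements."""
    from wntquant.pipeline import build_reference_parameters

    params_off, params_on, info = build_reference_parameters()
    return {"off": params_off, "on": params_on, **info}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
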