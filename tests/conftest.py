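import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noisevolve import synthio

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_events():
    """100k uncontaminated singlet events from the default reporter model."""
    return synthio.gen_events(synthio.ReporterModel(), 100_000, seed=1)


@pytest.fixture(scope="session")
def gated_events(clean_events):
    from noisevolve import cytometry

    return cytometry.gate_pipeline(clean_events)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
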