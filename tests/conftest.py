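import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bonn_like_record(rng):
    """A 4097-sample, 173.6 Hz noise segment (Bonn geometry)."""
    from ictal import SignalRecord
    return SignalRecord(rng.standard_normal(4097), 173.6, label="interictal",
                        source_id="fixture")
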