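import numpy as np
import pytest

from pvburst.synth import GroundTruth


@pytest.fixture(scope="session")
def small_truth() -> GroundTruth:
    """A down-scaled session (short rest/sessions, few units) for fast tests."""
    return GroundTruth(n_units=12, rest_duration_s=60.0,
                       session_duration_s=120.0, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
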