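import numpy as np
import pytest

from seizkit.protocol import StimProtocol
from seizkit.synth import SimConfig, simulate_session

# short session used throughout the suite: 2-min pre baseline, 3-min
# induction, 5-min post baseline
SHORT = StimProtocol(baseline_pre_s=120.0, baseline_post_s=300.0)


@pytest.fixture(scope="session")
def short_protocol() -> StimProtocol:
    return SHORT


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=123)


@pytest.fixture(scope="session")
def seizure_session(default_cfg, short_protocol):
    """One synthesized session (index 15) that carries a seizure."""
    rec, truth = simulate_session(default_cfg, short_protocol, 15,
                                  animal_index=0)
    assert truth.seizure_intervals
    return rec, truth


@pytest.fixture(scope="session")
def quiet_session(default_cfg, short_protocol):
    """A control session: paired pulses, no induction, no seizures."""
    rec, truth = simulate_session(default_cfg, short_protocol, 1,
                                  animal_index=1, with_induction=False)
    assert not truth.seizure_intervals
    return rec, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
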