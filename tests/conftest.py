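import numpy as np
import pytest

from v4popcode.synthetic import RingModelParams, SessionConfig


@pytest.fixture
def ring_params() -> RingModelParams:
    """A mid-size ring population with shared (radial) and private noise."""
    return RingModelParams(n_units=60, tuning_amplitude=10.0, baseline=4.0,
                           radial_noise_sd=0.25, private_noise_sd=2.0)


@pytest.fixture
def small_session_config() -> SessionConfig:
    """A reduced session (fewer trials/units) for fast pipeline tests."""
    return SessionConfig(
        ring=RingModelParams(n_units=14, tuning_amplitude=10.0,
                             tuning_width=0.10, baseline=4.0,
                             radial_noise_sd=0.2, private_noise_sd=2.0),
        change_trials_per_block=40, n_blocks=2)


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*divide.*")
        yield
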