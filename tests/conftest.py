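import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from b1select import SelectivePulseSpec, iburp2_envelope, make_b1_selective_pulse

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iburp2():
    return iburp2_envelope()


@pytest.fixture(scope="session")
def spec_200us(iburp2):
    """The reference construction: 100 kHz lock, 100 kHz modulation, 200 us, 1 us."""
    return SelectivePulseSpec(nu_sl=100e3, nu_mod=100e3, tau_p=200e-6, dt=1e-6, envelope=iburp2)


@pytest.fixture(scope="session")
def spec_1ms(iburp2):
    return SelectivePulseSpec(nu_sl=100e3, nu_mod=100e3, tau_p=1e-3, dt=1e-6, envelope=iburp2)


@pytest.fixture(scope="session")
def pulse_200us(spec_200us):
    return make_b1_selective_pulse(spec_200us)


@pytest.fixture(scope="session")
def pulse_1ms(spec_1ms):
    return make_b1_selective_pulse(spec_1ms)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
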