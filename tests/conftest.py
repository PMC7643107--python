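import pytest

from spiralsort import WATER, flow_condition, reference_device


@pytest.fixture
def channel():
    """The 500 um x 220 um, 5-outlet reference device."""
    return reference_device()


@pytest.fixture
def water():
    return WATER


@pytest.fixture
def flow_17(channel, water):
    """Operating point at 1.7 ml/min."""
    return flow_condition(1.7e-6 / 60.0, channel, water)
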