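import pytest

from trpgate import defaults
from trpgate.protocol import VoltageProtocol
from trpgate.synthetic import NoiseModel, generate_fret_trace, simulate_reference_cell


@pytest.fixture(scope="session")
def standard_protocol():
    return defaults.standard_protocol()


@pytest.fixture(scope="session")
def wt_reference_trace():
    """Noiseless wild-type cell under the standard pulse protocol with the
    shipped calibration (computed once; several tests read it)."""
    return simulate_reference_cell("WT")


@pytest.fixture(scope="session")
def single_pulse_protocol():
    return VoltageProtocol.single_pulse()


@pytest.fixture(scope="session")
def fret_reference_trace(single_pulse_protocol):
    """Noiseless FRET-reported PIP2 trace for one VSP episode."""
    return generate_fret_trace(defaults.WT_VSP, single_pulse_protocol, NoiseModel())


@pytest.fixture(scope="session")
def short_panel_protocol():
    """Two-pulse protocol used for panel simulations in tests (keeps each
    cell's simulation short while still allowing a 2-pulse cell summary)."""
    return VoltageProtocol.standard(n_pulses=2, first_onset_s=50.0)
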