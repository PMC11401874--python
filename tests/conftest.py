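import numpy as np
import pytest

from serogain.params import NetworkParams, NeuronParams
from serogain.netmodel import build_network
from serogain.synthgen import SynthSpec, generate_session


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def net_params():
    return NetworkParams()


@pytest.fixture(scope="session")
def network(net_params):
    return build_network(net_params, seed=1234)


@pytest.fixture(scope="session")
def single_unit_network():
    """One isolated excitatory unit (no recurrence)."""
    from serogain.netmodel import Network

    return Network(
        weights=np.zeros((1, 1)), is_excitatory=np.ones(1, dtype=bool), seed=0
    )


@pytest.fixture(scope="session")
def gain_session():
    """Synthetic session with a planted divisive gain change (d = 0.84) and no
    baseline photostimulation modulation; n = 100 units, 10 trials."""
    spec = SynthSpec(gain_d=0.84, offset_s=0.0, oi_mean=0.0, oi_sd=0.0)
    session, truth = generate_session(spec, seed=42)
    return spec, session, truth


@pytest.fixture(scope="session")
def oi_session():
    """Synthetic session with a uniform target opto-index of 0.5 and a high,
    narrow baseline-rate distribution (clean OI recovery)."""
    spec = SynthSpec(
        oi_mean=0.5, oi_sd=0.0, baseline_log_mean=float(np.log(8.0)), baseline_log_sd=0.0
    )
    session, truth = generate_session(spec, seed=7)
    return spec, session, truth
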