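import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from t1relax.phantom import default_phantom_spec, build_phantom, simulate_acquisition
from t1relax.signal_model import AcquisitionProtocol


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def young_subject(protocol):
    """One simulated young subject at default noise, reused across tests."""
    spec = default_phantom_spec()
    truth = build_phantom(spec, "young", seed=101, subject_id="sub-Y01")
    return simulate_acquisition(truth, protocol, noise_sigma=spec.noise_sigma, seed=202)


@pytest.fixture(scope="session")
def old_subject(protocol):
    spec = default_phantom_spec()
    truth = build_phantom(spec, "old", seed=303, subject_id="sub-O01")
    return simulate_acquisition(truth, protocol, noise_sigma=spec.noise_sigma, seed=404)
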