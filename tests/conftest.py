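import numpy as np
import pytest

from hsfibi.config import HsfConfig
from hsfibi.model import HsfIbi
from hsfibi.simulate import Scenario, generate_recording


@pytest.fixture(scope="session")
def cfg():
    return HsfConfig()


@pytest.fixture(scope="session")
def default_run():
    """One fitted reference run on the standard scenario, shared read-only."""
    scn = Scenario(seed=1)
    rec, beats, ibi_ms = generate_recording(scn)
    results = HsfIbi(rec).fit()
    return {"scenario": scn, "recording": rec, "beats": beats,
            "ibi_ms": ibi_ms, "results": results}


def make_pulse_train(period_s: float, duration_s: float, sr_hz: float,
                     width_s: float = 0.08, phase_s: float = 0.5):
    """Gaussian-pulse train: quasi-periodic test signal with known rate."""
    t = np.arange(int(duration_s * sr_hz)) / sr_hz
    sig = np.zeros_like(t)
    tc = phase_s
    while tc < duration_s:
        sig += np.exp(-0.5 * ((t - tc) / width_s) ** 2)
        tc += period_s
    return sig
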