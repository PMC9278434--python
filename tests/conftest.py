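import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from somnoresp import CalibrationInfo, analyze_recording, simulate_recording
from somnoresp.simulate import dta_protocol, sham_protocol


@pytest.fixture(scope="session")
def sham_short():
    """20 min sham recording: enough epochs to fit staging thresholds,
    cheap enough to share across tests."""
    protocol = sham_protocol(duration_s=1200.0, seed=7)
    return simulate_recording(protocol)


@pytest.fixture(scope="session")
def dta_recording():
    """One full 3 h lesioned-preset recording."""
    protocol = dta_protocol(seed=11)
    return simulate_recording(protocol)


@pytest.fixture(scope="session")
def dta_analysis(dta_recording):
    protocol = dta_recording.truth.protocol
    cal = CalibrationInfo(protocol.ml_per_unit, protocol.body_mass_kg)
    return analyze_recording(dta_recording.airflow, dta_recording.eeg,
                             dta_recording.emg, cal)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
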