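import numpy as np
import pytest

from nirsvot.config import PipelineConfig
from nirsvot.features import extract_session_features
from nirsvot.pipeline import preprocess_recording
from nirsvot.simulate import SimulationParams, simulate_session


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def schedule(config):
    return config.schedule()


@pytest.fixture(scope="session")
def noiseless_session(schedule):
    """One suprasystolic (complete-occlusion) session without noise or drift."""
    params = SimulationParams(noise_sd=0.0, drift_slope=0.0, seed=7)
    rec, truth = simulate_session(params, schedule)
    return params, rec, truth


@pytest.fixture(scope="session")
def noiseless_extracted(noiseless_session, schedule, config):
    """Filtered+normalized noiseless recording with extracted cycle features."""
    _, rec, truth = noiseless_session
    recn = preprocess_recording(rec, config)
    summary, cycles = extract_session_features(recn, schedule, "sub", "G3", "S1")
    return recn, truth, summary, cycles
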