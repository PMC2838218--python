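import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import measpike as mp

settings.register_profile(
    "ci", derandomize=True, max_examples=50, database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SUITE_SEED = 1


@pytest.fixture(scope="session")
def default_sim() -> mp.SimulationResult:
    """The reference study conditions: 60 s, 25 kHz, 600 events, 5 dB."""
    return mp.simulate(mp.SimulationConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def default_products(default_sim):
    """Full pipeline products on the reference simulation (zero-phase
    filtering, adaptive RMS-percentile estimator, validation on)."""
    filt = mp.bandpass_filter(default_sim.recording, zero_phase=True)
    thresholds = mp.make_estimator("adabandflt").run(filt)
    candidates = mp.detect_threshold_crossings(filt, thresholds)
    events, dropped = mp.validate_events(candidates, filt)
    waveforms = mp.extract_waveforms(filt, events)
    pca, model = mp.sort_waveforms(waveforms)
    return {
        "sim": default_sim,
        "filtered": filt,
        "thresholds": thresholds,
        "candidates": candidates,
        "events": events,
        "waveforms": waveforms,
        "pca": pca,
        "model": model,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
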