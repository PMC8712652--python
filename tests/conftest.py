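import numpy as np
import pytest

import nirsloc as nl


@pytest.fixture(scope="session")
def probe():
    return nl.load_probe_map()


@pytest.fixture(scope="session")
def lateral_session():
    """One default-condition subject session with the lateral-effect preset."""
    cfg = nl.SimulationConfig(seed=11, effect=nl.lateral_effect(),
                              confusion=nl.lateral_confusion())
    return nl.simulate_session(cfg)


@pytest.fixture(scope="session")
def high_snr_features():
    """ROI-level feature table from a strongly separable session."""
    cfg = nl.SimulationConfig(seed=5, effect=nl.high_snr_effect())
    rec, _, _ = nl.simulate_session(cfg)
    tt = nl.preprocess_recording(rec)
    return nl.extract_features(tt)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
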