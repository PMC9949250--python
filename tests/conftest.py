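import numpy as np
import pytest

from swrlab.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_lfp_session():
    """~55 min session with LFP: PRE 15 min, MAZE 10 min, POST 30 min."""
    cfg = SynthConfig(pre_duration=900, maze_duration=600, post_duration=1800,
                      n_pyramidal=40, n_interneuron=5, seed=1)
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def decoding_session():
    """Spike-only session with many place cells and frequent replays."""
    cfg = SynthConfig(n_pyramidal=100, n_interneuron=10, pre_duration=1200,
                      maze_duration=3600, post_duration=3600,
                      replay_fraction=0.5, seed=11)
    session, truth = generate_session(cfg, with_lfp=False)
    return cfg, session, truth


@pytest.fixture(scope="session")
def reactivation_session():
    """Spike-only NSD session at the default reactivation strength."""
    cfg = SynthConfig(n_pyramidal=80, n_interneuron=8, post_duration=9 * 3600.0,
                      replay_fraction=0.0, react_tau=2.5, seed=3)
    session, truth = generate_session(cfg, with_lfp=False)
    return cfg, session, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
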