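import numpy as np
import pytest

from cfassess.core import Epochs
from cfassess.preprocess import match_trial_counts, preprocess_recording
from cfassess.synthetic import EffectSpec, SimConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def responder_config(seed=0, n_blocks=3, depth=1.0, artifact_rate=0.0):
    """Simulation config with a left-hand ipsilateral high-beta ERS."""
    effects = []
    if depth:
        effects = [
            EffectSpec(
                "left", (25.0, 30.0), depth=depth,
                channel_side="ipsilateral", latency=1.0, duration=1.0,
            )
        ]
    return SimConfig(
        n_blocks=n_blocks, seed=seed, effects=effects, artifact_rate=artifact_rate
    )


@pytest.fixture(scope="session")
def responder_epochs():
    """Preprocessed bipolar epochs from the standard responder simulation,
    matched to the 36/36/34 trial counts."""
    sim = simulate_recording(responder_config(seed=7))
    epochs, _ = preprocess_recording(sim.recording, reject=False)
    return match_trial_counts(
        epochs, {"left": 36, "right": 36, "rest": 34}, seed=7
    )


@pytest.fixture(scope="session")
def null_epochs():
    """Epochs from a simulation with no task effects."""
    sim = simulate_recording(responder_config(seed=11, depth=0.0, n_blocks=2))
    epochs, _ = preprocess_recording(sim.recording, reject=False)
    return epochs


@pytest.fixture
def sine_epochs():
    """Tiny deterministic bipolar epochs: pure 10 Hz sinusoid."""
    sfreq = 100.0
    t = np.arange(600) / sfreq
    x = np.sin(2 * np.pi * 10 * t)
    data = np.tile(x, (4, 2, 1))
    return Epochs(
        data, sfreq, ["C3'", "C4'"], ["left", "left", "rest", "rest"],
        montage="bipolar",
    )
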