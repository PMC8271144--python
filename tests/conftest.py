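import numpy as np
import pytest

from spikestate.model import BehaviorEpoch, SessionRecord, SpikeTrain, WaveformSet
from spikestate.simulate import SimulationConfig, generate_session


@pytest.fixture
def tiny_session():
    """Three hand-built units, two epochs; small enough to reason about."""
    trains = [
        SpikeTrain("a", [0.5, 1.2, 2.9, 4.0], 0.0, 6.0),
        SpikeTrain("b", [3.3], 0.0, 6.0),
        SpikeTrain("c", np.empty(0), 0.0, 6.0),
    ]
    rng = np.random.default_rng(0)
    wfs = {
        uid: WaveformSet(uid, rng.normal(0, 1, (4, 48)), 30_000.0)
        for uid in ("a", "b", "c")
    }
    epochs = [BehaviorEpoch("RS", 0.0, 3.0), BehaviorEpoch("M", 3.0, 6.0)]
    return SessionRecord("tiny", "REST", trains, wfs, epochs)


@pytest.fixture(scope="session")
def default_session():
    """One medium synthetic session shared by read-only tests."""
    cfg = SimulationConfig(n_units=60, total_duration=300.0, seed=1)
    return generate_session(cfg)
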