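import numpy as np
import pytest

from teamsync.types import BeatSeries, PhaseSpan


@pytest.fixture
def constant_beats():
    """Factory: metronome-regular beats covering [0, duration_s]."""

    def make(nn_ms: float = 1000.0, duration_s: float = 300.0, pid: str = "p1") -> BeatSeries:
        n = int(duration_s * 1000.0 // nn_ms)
        return BeatSeries(pid, np.arange(n + 1) * nn_ms)

    return make


@pytest.fixture
def beats_from_nn():
    """Factory: beats with the given NN sequence (ms), first peak at t0_ms."""

    def make(nn_ms, t0_ms: float = 0.0, pid: str = "p1") -> BeatSeries:
        peaks = np.concatenate(([t0_ms], t0_ms + np.cumsum(np.asarray(nn_ms, dtype=float))))
        return BeatSeries(pid, peaks)

    return make


@pytest.fixture
def scenario_span():
    return PhaseSpan("street", 0.0, 480.0, order=1)
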