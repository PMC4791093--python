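import numpy as np
import pytest

from dsemicro.protocol import (
    PulseArrangement,
    build_effective_waveform,
    infer_polarities,
    table1_protocol,
)


@pytest.fixture(scope="session")
def protocol6():
    """Table-1 protocol with a small direction set (fast tests)."""
    return table1_protocol(n_directions=6)


@pytest.fixture(scope="session")
def protocol90():
    """Full 90-direction protocol."""
    return table1_protocol()


@pytest.fixture(scope="session")
def waveforms(protocol6):
    """Effective waveforms of the weighted Table-1 arrangements, keyed 2..5."""
    return {
        i + 1: build_effective_waveform(protocol6.arrangements[i])
        for i in protocol6.weighted_indices
    }


def pgse_arrangement(delta_ms=10.0, Delta_ms=40.0, G=0.035, echo_time_ms=60.0):
    """A classical pulsed-gradient pair as a two-pulse arrangement."""
    arr = PulseArrangement(
        onsets=(0.0, Delta_ms),
        lengths=(delta_ms, delta_ms),
        amplitude=G,
        echo_time=echo_time_ms,
    )
    return infer_polarities(arr)


@pytest.fixture(scope="session")
def free_substrate():
    """Effectively cylinder-free periodic cell (one negligible cylinder)."""
    from dsemicro.simulator import Substrate

    return Substrate(
        centers=np.array([[1e-3, 1e-3]]),
        radii=np.array([1e-9]),
        cell=(2e-3, 2e-3),
        diffusivity=1.7e-9,
    )
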