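import numpy as np
import pytest

from laser_rfa import (
    AnalysisWindow,
    ExcitationSchedule,
    ModalMode,
    NoiseModel,
    simulate_record,
)


@pytest.fixture
def window():
    return AnalysisWindow()  # 4.5 ms purge, 100 ms segments


@pytest.fixture
def single_mode_record():
    """Noiseless 16-pulse record of a single 2500 Hz mode at 50 kHz."""

    def make(frequency=2500.0, zeta=0.02, amplitude=1.0, noise=None, seed=0):
        return simulate_record(
            [ModalMode(frequency, zeta, amplitude)],
            ExcitationSchedule(),
            noise or NoiseModel(),
            sampling_rate=50_000.0,
            seed=seed,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
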