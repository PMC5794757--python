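import numpy as np
import pytest

from rockpsg.core import EpochedHypnogram
from rockpsg.synthetic import SimulationConfig


def random_hypnogram(rng: np.random.Generator, n_epochs: int = 30) -> EpochedHypnogram:
    stages = rng.choice(["W", "N1", "N2", "N3", "REM"], size=n_epochs)
    flags = rng.random(n_epochs) < 0.1
    return EpochedHypnogram(stages=stages, artifact_flags=flags)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_night_config():
    """1-h night at 128 Hz with quiet background and high-SNR events."""
    return SimulationConfig(
        night_duration=3600.0,
        sampling_rate=128.0,
        seed=3,
        spindle_amp_range=(35.0, 60.0),
        so_amp_range=(55.0, 90.0),
        artifact_rate=0.0,
        stage_rms={"W": 10.0, "N1": 8.0, "N2": 8.0, "N3": 10.0, "REM": 10.0},
    )
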