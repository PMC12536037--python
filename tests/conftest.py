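import warnings

import pytest

from pmexposure.config import WorldConfig
from pmexposure.context import StudyArea
from pmexposure.synthetic import generate_world

warnings.filterwarnings("ignore", category=UserWarning, module="pmexposure")


@pytest.fixture(scope="session")
def noiseless_world():
    """Small cohort with every noise source off: full ground-truth recovery."""
    cfg = WorldConfig(
        seed=11,
        n_participants=3,
        n_days=2,
        gps_noise_sd=0.0,
        gps_gap_rate=0.0,
        sensor_noise_sd=0.0,
        ambient_ar_sd=0.0,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noisy_world():
    """Small cohort at the default noise settings (10 m GPS, 2% gaps)."""
    cfg = WorldConfig(seed=12, n_participants=3, n_days=2)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noiseless_area(noiseless_world):
    return StudyArea.from_landscape(noiseless_world.landscape)


@pytest.fixture(scope="session")
def noisy_area(noisy_world):
    return StudyArea.from_landscape(noisy_world.landscape)
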