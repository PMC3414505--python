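import numpy as np
import pytest

from iscval import DesignSpec, HRFParams, SimulationSpec, simulate_cohort
from iscval.noise import pink_noise_matrix


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def hrf():
    return HRFParams()


@pytest.fixture(scope="session")
def small_cohort():
    """6-subject cohort on a 10^3 grid at high SNR; shared across tests."""
    spec = SimulationSpec(grid=(10, 10, 10), n_subjects=6, snr=0.01, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noise_cohort_ts():
    """Pure pink-noise multi-subject series, (8 subjects, 512 voxels, 84)."""
    root = np.random.SeedSequence(2024)
    data = np.stack(
        [
            pink_noise_matrix(512, 84, np.random.default_rng(ss))
            for ss in root.spawn(8)
        ]
    )
    return data
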