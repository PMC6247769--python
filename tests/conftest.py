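import numpy as np
import pytest

from plasmakit.simulate import SimulationConfig, simulate_sample, simulate_normal_profiles


@pytest.fixture(scope="session")
def msat_bank():
    """Shared microsatellite material: normals, MSI and MSS sample profiles."""
    msi_cfg = SimulationConfig(seed=5, n_patients=12, true_tf=1.0, msi_status=True)
    mss_cfg = SimulationConfig(seed=6, n_patients=12, true_tf=1.0, msi_status=False)
    return {
        "normals": [simulate_normal_profiles(mss_cfg, i) for i in range(8)],
        "msi": [simulate_sample(msi_cfg, i) for i in range(12)],
        "mss": [simulate_sample(mss_cfg, i) for i in range(12)],
    }


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(seed=17, n_patients=30)
    return cfg, [simulate_sample(cfg, i) for i in range(cfg.n_patients)]


@pytest.fixture
def rng():
    return np.random.default_rng(123)
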