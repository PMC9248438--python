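import numpy as np
import pytest

from hypoximap.config import PhantomConfig, StudyConfig

#: Table-of-record parameter sets used across tests (D, D* in mm²/s).
TUMOR_MEANS = dict(d=419.50e-6, dstar=2850.23e-6, f=0.5109, r2star=38.24)
NORMAL_MEANS = dict(d=414.21e-6, dstar=2755.02e-6, f=0.4629, r2star=36.74)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_phantom_config():
    """Reduced-geometry phantom used where full size is unnecessary."""
    return PhantomConfig(
        shape=(48, 48, 8),
        brain_semiaxes_mm=(4.8, 3.9, 3.2),
        tumor_center_offset_mm=(-1.3, 0.0, 0.0),
        tumor_volume_mm3=57.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study_config(small_phantom_config):
    return StudyConfig(n_animals=1, tumor_volume_sd_mm3=0.0,
                       phantom=small_phantom_config, write_volumes=False,
                       seed=11)
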