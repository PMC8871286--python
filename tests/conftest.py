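import numpy as np
import pytest

from dixonvol.grid import VolumeGrid
from dixonvol.mrs import AcquisitionConstants
from dixonvol.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def acq() -> AcquisitionConstants:
    return AcquisitionConstants()


@pytest.fixture(scope="session")
def small_mask() -> VolumeGrid:
    """A deterministic small liver mask on a 24x24x16, 4x4x5 mm lattice."""
    from dixonvol.synthetic import generate_liver_mask

    return generate_liver_mask((24, 24, 16), (4.0, 4.0, 5.0), seed=42)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Two subjects per arm on a small grid: fast end-to-end plumbing."""
    return GeneratorConfig(
        n_per_arm={"MUFA": 2, "MULTIFACTORIAL": 2},
        grid_shape=(12, 12, 10),
        voxel_size=(6.0, 6.0, 8.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
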