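import numpy as np
import pytest

from dmirecon import AcquisitionGrid, PhantomSpec

SEED = 20240917


@pytest.fixture(scope="session")
def grid() -> AcquisitionGrid:
    """Full acquisition grid of the study (12 x 18 x 15, 1024 points)."""
    return AcquisitionGrid()


@pytest.fixture(scope="session")
def small_grid() -> AcquisitionGrid:
    """Tiny grid for operator-level tests."""
    return AcquisitionGrid(nx=8, ny=8, nz=3, n_time=32)


@pytest.fixture(scope="session")
def small_phantom() -> PhantomSpec:
    """Down-scaled phantom that still has all four compartments."""
    return PhantomSpec(highres_dims=(48, 48, 9), fat_rim_voxels=3)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def study_inputs():
    """Deterministic full-size study inputs shared across the session."""
    from dmirecon.experiment import ExperimentConfig, prepare_inputs

    return prepare_inputs(ExperimentConfig(master_seed=SEED))
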