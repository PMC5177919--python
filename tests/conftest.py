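import numpy as np
import pytest

from icosaflow import (AcquisitionSettings, PhantomSpec, generate_phantom,
                       simulate_acquisition, suggest_venc)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale jet phantom spec: short axial window around the stenosis."""
    return PhantomSpec(axial_extent=(-1.2, 3.0), seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec, n_snapshots=8)


@pytest.fixture(scope="session")
def small_acquisition(small_phantom):
    venc = suggest_venc(small_phantom)
    settings = AcquisitionSettings(voxel_size=1e-3, venc=venc)
    return simulate_acquisition(small_phantom, settings)


@pytest.fixture(scope="session")
def coarse_spec():
    """Coarse-grid phantom for ensemble-statistics tests (cheap snapshots)."""
    return PhantomSpec(grid_spacing=1e-3, axial_extent=(-1.0, 2.0), seed=3)


@pytest.fixture(scope="session")
def coarse_phantom_400(coarse_spec):
    return generate_phantom(coarse_spec, n_snapshots=400, snapshot_interval=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
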