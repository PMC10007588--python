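import numpy as np
import pytest

from gammacal.detector import DetectorGeometry, SourceSpec, simulate_true_sm
from gammacal.geometry import make_coarse_grid


@pytest.fixture(scope="session")
def small_geometry() -> DetectorGeometry:
    """4x4x2 toy detector used by ray-tracing and container tests."""
    return DetectorGeometry(
        n_transverse=4, n_depth_bins=2, sub_block_size=2, crystal_pitch=4.0,
        crystal_depth=8.0, mu=0.15, edge_loss=0.8,
    )


@pytest.fixture(scope="session")
def small_true_sm(small_geometry):
    """Noiseless coarse-grid system matrix of the toy detector (360 x 32)."""
    source = SourceSpec("Tc99m", mu=0.15, events_per_point=1.0e5)
    return simulate_true_sm(small_geometry, source, make_coarse_grid())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
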