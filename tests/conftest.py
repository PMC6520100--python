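import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import boldfractal as bf


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Compact phantom used across modules: 32-voxel grid, lateral tumor."""
    return bf.PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor_center_mm=(16.0, 16.0, 0.0),
        tumor_radius_mm=5.5,
        n_subjects=1,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return bf.simulate_phantom_subject(small_phantom_spec)


@pytest.fixture(scope="session")
def phantom_gm(small_phantom):
    from boldfractal.synthetic import GREY_MATTER

    return small_phantom.tissue == GREY_MATTER


@pytest.fixture(scope="session")
def truth_hmap(small_phantom, phantom_gm):
    """Ground-truth H volume wrapped as a fully-valid map over brain voxels."""
    valid = np.isfinite(small_phantom.truth_h)
    return bf.HurstMap(values=small_phantom.truth_h, validity=valid)


@pytest.fixture(scope="session")
def random_small_graphs():
    """100 random connected-ish weighted graphs with n <= 5 (fixed seed)."""
    rng = np.random.default_rng(42)
    graphs = []
    while len(graphs) < 100:
        n = int(rng.integers(3, 6))
        W = rng.uniform(0.1, 2.0, size=(n, n))
        W = np.triu(W, 1)
        # random sparsification keeps some disconnected cases out
        mask = rng.random((n, n)) < 0.8
        W = W * np.triu(mask, 1)
        W = W + W.T
        graphs.append(W)
    return graphs
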