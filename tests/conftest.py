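import numpy as np
import pytest

from avacrit import DGParams, RingModelSpec, ring_dg_params


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def exchangeable_ring_6():
    """Homogeneous (critical-limit) ring model, n=6."""
    return ring_dg_params(RingModelSpec(6, 0.5, float("inf"), 0.2))


@pytest.fixture
def heterogeneous_dg_4():
    """A small DG model with unequal rates and correlations."""
    delta = np.array([-0.8, -0.3, 0.1, -0.5])
    Lam = np.array([
        [1.0, 0.3, 0.1, 0.2],
        [0.3, 1.0, 0.25, 0.15],
        [0.1, 0.25, 1.0, 0.35],
        [0.2, 0.15, 0.35, 1.0],
    ])
    return DGParams(delta, Lam)
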