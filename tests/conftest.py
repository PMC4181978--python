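import numpy as np
import pytest

from fprs import GridSpec, SuitabilityGrid


@pytest.fixture
def spec():
    """A small 4x3 grid: 1-degree cells, SW corner at (100 E, 30 N)."""
    return GridSpec(n_cols=4, n_rows=3, x_origin=100.0, y_origin=30.0, cell_size=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20140930)


def grid_from(spec, values, mask=None):
    return SuitabilityGrid(spec, np.asarray(values, dtype=float), mask)


def random_grid(rng, spec, p_zero=0.3):
    """Random membership grid with a share of exact-zero cells."""
    v = rng.random(spec.shape)
    v[rng.random(spec.shape) < p_zero] = 0.0
    return SuitabilityGrid(spec, v)
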