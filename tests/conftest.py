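import numpy as np
import pytest

from thermomics.thermal_io import HeatMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def wrap_heat_matrix(X: np.ndarray) -> HeatMatrix:
    """Wrap a raw p x n matrix as a HeatMatrix with a p x 1 ROI."""
    X = np.asarray(X, dtype=np.float64)
    p, n = X.shape
    return HeatMatrix(X=X, row_mean=np.zeros(p), roi=(0, 0, p, 1),
                      source_shape=(p, 1))


@pytest.fixture
def tiny_hm(rng):
    """Random full-rank 6 x 4 heat matrix."""
    return wrap_heat_matrix(rng.standard_normal((6, 4)))
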