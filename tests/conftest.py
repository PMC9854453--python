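import numpy as np
import pandas as pd
import pytest

from riverrange.grid import Grid
from riverrange.synthetic import LandscapeConfig, make_landscape, simulate_truth


def make_occ(xs, ys, uncertainty=None, years=None):
    """Small occurrence-table builder for tests."""
    n = len(xs)
    return pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "x": np.asarray(xs, float),
            "y": np.asarray(ys, float),
            "year": years if years is not None else np.full(n, 2020),
            "uncertainty_m": uncertainty if uncertainty is not None else np.zeros(n),
        }
    )


@pytest.fixture
def grid16():
    return Grid(values=np.zeros((16, 16)), cell_size_m=1000.0)


@pytest.fixture(scope="session")
def bundle16():
    return make_landscape(LandscapeConfig(n_rows=16, n_cols=16, seed=11))


@pytest.fixture(scope="session")
def truth16(bundle16):
    return simulate_truth(bundle16)


@pytest.fixture(scope="session")
def strong_bundle():
    """32x32 landscape with a contrasted logistic truth (|beta| = 2)."""
    return make_landscape(
        LandscapeConfig(
            n_rows=32,
            n_cols=32,
            seed=5,
            buffer_radius_m=5000.0,
            truth_beta={
                "intercept": -4.0,
                "temperature": 2.0,
                "precipitation": -2.0,
            },
        )
    )
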