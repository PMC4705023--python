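import numpy as np
import pandas as pd
import pytest

from emavar.data_io import EmaDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bivariate_dataset(rng):
    """A stable bivariate VAR(1) draw with known coefficients, T=100."""
    from emavar.synthetic import SyntheticSpec, simulate

    spec = SyntheticSpec(
        variable_names=("x", "y"),
        lag_matrices=(((0.5, 0.0), (-0.3, 0.4)),),
        intercepts=(0.0, 0.0),
        noise_covariance=((1.0, 0.0), (0.0, 1.0)),
        T=100,
        seed=7,
    )
    dataset, truth = simulate(spec)
    return dataset, truth


def make_dataset(values, columns=("x", "y"), dates_from=None):
    frame = pd.DataFrame(np.asarray(values, dtype=float), columns=list(columns)[: np.asarray(values).shape[1]])
    dates = None
    if dates_from is not None:
        dates = pd.Series(pd.date_range(dates_from, periods=len(frame), freq="D"))
    return EmaDataset(values=frame, dates=dates)
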