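import numpy as np
import pandas as pd
import pytest

from gnhswitch import DailySeries, MSDRParameters, nz_parameters


@pytest.fixture(scope="session")
def nz_params() -> MSDRParameters:
    """Published two-state regime parameters used as generating truth."""
    return nz_parameters()


@pytest.fixture
def make_series():
    """Factory wrapping raw values in a dated DailySeries."""

    def _make(values, start="2019-05-11", name="gnh") -> DailySeries:
        values = np.asarray(values, dtype=float)
        dates = pd.date_range(start, periods=len(values), freq="D")
        return DailySeries(dates, values, name)

    return _make


@pytest.fixture(scope="session")
def well_separated() -> MSDRParameters:
    """Cleanly separated regimes for recovery and classification checks."""
    return MSDRParameters(
        means=[0.0, 5.0],
        sigmas=[1.0, 1.0],
        transition=[[0.95, 0.05], [0.05, 0.95]],
    )
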