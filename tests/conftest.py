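import numpy as np
import pytest

from phmsr import synthetic_data as sdata


@pytest.fixture(scope="session")
def phantom():
    """A standard 4-cusp molar phantom shared across the suite."""
    return sdata.make_tooth_phantom(4, 10.0, seed=1)


@pytest.fixture(scope="session")
def scan_cloud(phantom):
    return sdata.make_scan_cloud(phantom, density_per_mm2=60.0, seed=11)


@pytest.fixture(scope="session")
def cbct_clouds(phantom):
    """(crown, pulp) CBCT-like pair without gross degradation."""
    return sdata.make_cbct_cloud(phantom, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
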