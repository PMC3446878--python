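
import pandas as pd
import pytest

from evisoscape.model import IsoModelParams, IsoObservation
from evisoscape.synthetic import REFERENCE_CONSTANTS, SimConfig, make_network_dataset


@pytest.fixture(scope="session")
def s1_params():
    return IsoModelParams(*REFERENCE_CONSTANTS["s1"])


@pytest.fixture(scope="session")
def s13_params():
    return IsoModelParams(*REFERENCE_CONSTANTS["s13"])


def make_obs(x, y, site_id="test", start="2007-01-01", spacing_days=30):
    """Build observation records from covariate/response arrays."""
    t0 = pd.Timestamp(start)
    out = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        a = t0 + pd.Timedelta(days=spacing_days * i)
        out.append(IsoObservation(site_id, (a, a + pd.Timedelta(days=16)),
                                  float(xi), float(yi)))
    return out


@pytest.fixture(scope="session")
def mk_obs():
    return make_obs


@pytest.fixture(scope="session")
def quiet_network():
    """Noise-free 13-site, 3-season virtual network (expensive: share it)."""
    return make_network_dataset(SimConfig().quiet())


@pytest.fixture(scope="session")
def small_quiet_network():
    return make_network_dataset(SimConfig(n_sites=4, years=2).quiet())
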