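import numpy as np
import pytest

from badhkin import (
    ArrheniusParams,
    PhProfileModel,
    PhProfileParams,
    RateLawModel,
    RateLawParams,
    default_decay_segments,
    table2_fixtures,
)

S_GRID_12 = np.linspace(0.25, 8.0, 12)


@pytest.fixture(scope="session")
def fixtures():
    """Published apparent kinetic parameter sets."""
    return table2_fixtures()


@pytest.fixture(scope="session")
def balc_nad_params(fixtures):
    """Benzyl alcohol oxidation with NAD+: the interior-optimum MM_SI set."""
    return fixtures["BAlc ox NAD+ pH 8.0"]


@pytest.fixture(scope="session")
def nadp_hill_params(fixtures):
    """NADP+ reduction: cooperative Hill-with-inhibition set on the
    Km = Kis constraint boundary."""
    return fixtures["NADP+ red pH 6.5"]


@pytest.fixture(scope="session")
def bell_params():
    return PhProfileParams(PhProfileModel.BELL, vlim=100.0, pka=5.5, pkb=7.0)


@pytest.fixture(scope="session")
def arrhenius_params():
    return ArrheniusParams(prefactor=1.0e6, ea=25.8)


@pytest.fixture(scope="session")
def decay_segments(arrhenius_params):
    return default_decay_segments(arrhenius_params)
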