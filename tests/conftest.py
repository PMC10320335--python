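import numpy as np
import pytest

from colext import PresenceSeries, SiteObservations
from colext.synthetic import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures()


@pytest.fixture(scope="session")
def likelihood_series(fixtures) -> PresenceSeries:
    """3 taxa x 4 irregular times; small enough for path enumeration."""
    return fixtures["likelihood"]


@pytest.fixture(scope="session")
def two_regime(fixtures):
    """Occupancy-abundance table with a known break at occupancy 0.5."""
    return fixtures["two_regime"]


@pytest.fixture(scope="session")
def duplicated_site_series(fixtures) -> PresenceSeries:
    return fixtures["duplicated_site"]


@pytest.fixture()
def two_taxon_series() -> PresenceSeries:
    """Tiny two-taxon series with both event directions observed."""
    times = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    det = np.array(
        [
            [1, 1, 1, 0, 0, 1],
            [0, 0, 1, 1, 1, 1],
        ],
        dtype=bool,
    )
    return PresenceSeries(("a", "b"), {"s": SiteObservations(times, det)})
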