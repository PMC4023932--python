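import numpy as np
import pytest

from morphmap import filter_geocoded, generate_records, project, reference_scenario


@pytest.fixture(scope="session")
def reference_records():
    """Geocoded + projected records of the shipped reference scenario."""
    scenario = reference_scenario(20140516)
    rs = generate_records(scenario)
    geo = filter_geocoded(rs)
    lat = np.array([r.latitude for r in geo])
    lon = np.array([r.longitude for r in geo])
    return scenario, geo, project(lat, lon)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_localities(rng, n=200, extent=1e6):
    """Random locality coordinates with integer specimen counts >= 1."""
    xy = rng.uniform(0, extent, size=(n, 2))
    values = 1 + rng.poisson(2.0, n)
    return xy, values.astype(float)
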