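from __future__ import annotations

import numpy as np
import pytest

from spatialaccess import (
    AreaUnit,
    DecaySchedule,
    ProviderSite,
    RegionConfig,
    TravelTimeMatrix,
    generate_region,
)

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


def make_area(area_id="A1", pop=1000.0, car=850.0, transit=100.0, walk=50.0,
              ruca="metropolitan", adi="Q1", x=0.0, y=0.0) -> AreaUnit:
    return AreaUnit(area_id=area_id, x=x, y=y, population=pop,
                    commuters_car=car, commuters_transit=transit, commuters_walk=walk,
                    rural_urban_class=ruca, deprivation_quartile=adi)


def make_site(site_id="S1", classification="primary_care", period="2016Q4",
              x=0.0, y=0.0, capacity=1.0, provider_id=None) -> ProviderSite:
    return ProviderSite(site_id=site_id, provider_id=provider_id or f"P-{site_id}",
                        classification=classification, x=x, y=y,
                        period=period, capacity=capacity)


def random_instance(rng: np.random.Generator, n_areas=None, n_sites=None):
    """A random small E2SFCA instance: areas, sites, matrix, schedule."""
    n = int(n_areas if n_areas is not None else rng.integers(1, 21))
    m = int(n_sites if n_sites is not None else rng.integers(1, 11))
    areas = [make_area(f"A{i:03d}", pop=float(rng.integers(0, 5000))) for i in range(n)]
    sites = [make_site(f"S{j:03d}", capacity=float(rng.uniform(0.5, 3.0))) for j in range(m)]
    minutes = rng.uniform(0, 45, size=(n, m))
    minutes[rng.uniform(size=(n, m)) < 0.1] = np.inf  # some unreachable pairs
    matrix = TravelTimeMatrix("car", [a.area_id for a in areas],
                              [s.site_id for s in sites], minutes)
    return areas, sites, matrix, DecaySchedule()


@pytest.fixture(scope="session")
def metro_region():
    """Default-profile synthetic region, large enough for stratified power."""
    return generate_region(RegionConfig(n_areas=480, seed=11))
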