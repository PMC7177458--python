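import numpy as np
import pandas as pd
import pytest

from schoolcommute.network import StreetNetwork
from schoolcommute.simulate import (
    CityConfig,
    TABLE_SIGNS_PRESET,
    generate_city,
    generate_participants,
)


def make_grid(blocks: int = 4, spacing: float = 100.0) -> StreetNetwork:
    """(blocks+1)^2-node square grid with uniform edge length ``spacing``."""
    n = blocks + 1
    nodes = {i * n + j: (i * spacing, j * spacing)
             for i in range(n) for j in range(n)}
    edges = []
    for i in range(n):
        for j in range(n):
            if i + 1 < n:
                edges.append((i * n + j, (i + 1) * n + j, spacing))
            if j + 1 < n:
                edges.append((i * n + j, i * n + j + 1, spacing))
    return StreetNetwork(nodes, edges)


@pytest.fixture(scope="session")
def grid_net() -> StreetNetwork:
    return make_grid(4, 100.0)


@pytest.fixture(scope="session")
def big_grid() -> StreetNetwork:
    # 10x10 blocks = 121 nodes, within the brute-force oracle budget
    return make_grid(10, 100.0)


# compact but structurally sound: enough schools per age group that the
# median-dummied school measures vary within each stratum
SMALL_CITY_CFG = CityConfig(
    blocks=16, n_children=300, n_adolescents=600,
    n_primary=5, n_secondary=8, n_mixed=2,
    school_min_sep_m=350.0, seed=7,
)


@pytest.fixture(scope="session")
def small_city():
    return generate_city(SMALL_CITY_CFG)


@pytest.fixture(scope="session")
def small_roster(small_city):
    roster, truth = generate_participants(SMALL_CITY_CFG, small_city,
                                          TABLE_SIGNS_PRESET)
    return roster, truth


@pytest.fixture(scope="session")
def small_exposures(small_city, small_roster):
    from schoolcommute.coding import apply_exclusions
    from schoolcommute.exposure import build_exposure_table

    roster, _ = small_roster
    retained, _ = apply_exclusions(roster)
    table, log = build_exposure_table(retained, small_city.schools,
                                      small_city.net, small_city.parcels)
    return table, log
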