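"""Predictor construction: PRD, densities, entropy index, exposure assembly."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from schoolcommute.exposure import (
    LAND_USE_CLASSES,
    Parcel,
    build_exposure_table,
    compute_buffer_measures,
    intersection_density,
    mixed_use_index,
    prd,
    resident_density,
    z_scores,
)
from schoolcommute.network import StreetNetwork, shortest_network_distance

from conftest import make_grid


# ---------------------------------------------------------------------- PRD

def test_prd_grid_diagonal_is_sqrt2():
    assert prd(400.0, 282.84) == pytest.approx(math.sqrt(2), abs=1e-3)


def test_prd_straight_street_identity():
    assert prd(750.0, 750.0) == pytest.approx(1.0)


def test_prd_below_one_warns_but_returns():
    with pytest.warns(UserWarning, match="PRD"):
        assert prd(90.0, 100.0) == pytest.approx(0.9)


def test_prd_home_at_school_rejected():
    with pytest.raises(ValueError):
        prd(100.0, 0.0)


def test_blocked_superblock_raises_prd():
    """A non-crossable block forces a detour: same endpoints, higher PRD."""
    full = make_grid(4, 100.0)
    centre = 2 * 5 + 2  # (200, 200)
    open_edges = [(u, v, w) for u, v, w in full.edges
                  if centre not in (u, v)]
    blocked = StreetNetwork({n: c for n, c in full.nodes.items() if n != centre},
                            open_edges)
    home, school = (0.0, 200.0), (400.0, 200.0)
    d_full = shortest_network_distance(full, home, school)
    d_blocked = shortest_network_distance(blocked, home, school)
    e = 400.0
    assert d_full == pytest.approx(400.0)
    assert prd(d_blocked, e) > prd(d_full, e)


# ---------------------------------------------------------------------- densities

def test_density_examples_and_errors():
    assert resident_density(0, 10.0) == 0.0
    assert resident_density(500, 10.0) == 50.0
    assert intersection_density(40, 10.0) == 4.0
    with pytest.raises(ValueError):
        resident_density(10, 0.0)
    with pytest.raises(ValueError):
        intersection_density(-1, 5.0)


@given(st.floats(1.0, 1e4), st.floats(0.1, 1e3), st.floats(0.5, 20.0))
@settings(max_examples=50, deadline=None)
def test_density_homogeneous_degree_minus_one(residents, area, c):
    assert resident_density(residents, area * c) == \
        pytest.approx(resident_density(residents, area) / c)


# ---------------------------------------------------------------------- entropy

def test_entropy_single_use_is_zero():
    assert mixed_use_index({"residential": 1000.0}) == pytest.approx(0.0)


def test_entropy_six_equal_uses_is_one():
    areas = {c: 500.0 for c in LAND_USE_CLASSES}
    assert mixed_use_index(areas) == pytest.approx(1.0)


def test_entropy_two_class_hand_value():
    # -(0.75 ln 0.75 + 0.25 ln 0.25)/ln 6 = 0.313846...
    areas = {"residential": 750.0, "retail": 250.0}
    assert mixed_use_index(areas, k=6) == pytest.approx(0.3138, abs=2e-4)


def test_entropy_all_zero_rejected():
    with pytest.raises(ValueError):
        mixed_use_index({c: 0.0 for c in LAND_USE_CLASSES})


@given(st.lists(st.floats(0.1, 1e5), min_size=2, max_size=6, unique=True),
       st.floats(0.01, 100.0))
@settings(max_examples=60, deadline=None)
def test_entropy_permutation_and_scale_invariant(areas, c):
    classes = list(LAND_USE_CLASSES[:len(areas)])
    base = mixed_use_index(dict(zip(classes, areas)))
    shuffled = mixed_use_index(dict(zip(reversed(classes), areas)))
    scaled = mixed_use_index(dict(zip(classes, [a * c for a in areas])))
    assert shuffled == pytest.approx(base, rel=1e-9)
    assert scaled == pytest.approx(base, rel=1e-6)


# ---------------------------------------------------------------------- z-scores

def test_z_scores_population_convention():
    z = z_scores([1.0, 2.0, 3.0])
    assert z == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-5)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)


def test_z_scores_constant_rejected():
    with pytest.raises(ValueError):
        z_scores([5.0, 5.0, 5.0])


# ---------------------------------------------------------------------- buffer measures

def test_areal_weighting_matches_parcel_scan(big_grid):
    """Residents inside the footprint tally by intersected fraction."""
    rng = np.random.default_rng(5)
    parcels = []
    for i in range(10):
        for j in range(10):
            x0, y0 = i * 100.0 + 10, j * 100.0 + 10
            poly = Polygon([(x0, y0), (x0 + 80, y0), (x0 + 80, y0 + 80),
                            (x0, y0 + 80)])
            parcels.append(Parcel(
                parcel_id=f"p{i}{j}", polygon=poly,
                use_class=LAND_USE_CLASSES[(i + j) % 6],
                floor_area_m2=poly.area,
                residents=float(rng.integers(0, 200))))
    bm = compute_buffer_measures(big_grid, "s", (450.0, 450.0), 500.0, parcels)
    from schoolcommute.network import network_buffer
    fp = network_buffer(big_grid, (450.0, 450.0), 500.0).footprint
    expected = sum(p.residents * p.polygon.intersection(fp).area / p.polygon.area
                   for p in parcels)
    assert bm.residents == pytest.approx(expected, rel=1e-9)
    assert bm.residents_density == pytest.approx(expected / bm.area_ha, rel=1e-9)


# ---------------------------------------------------------------------- table assembly

def _mini_inputs():
    net = make_grid(4, 100.0)
    schools = pd.DataFrame({"school_id": ["s0"], "x": [200.0], "y": [200.0]})
    parcels = [Parcel("p0", Polygon([(10, 10), (390, 10), (390, 390), (10, 390)]),
                      "residential", 10_000.0, residents=800.0)]
    return net, schools, parcels


def test_empty_participants_gives_empty_table():
    net, schools, parcels = _mini_inputs()
    empty = pd.DataFrame(columns=["pid", "age_group", "home_x", "home_y",
                                  "school_id", "trips"])
    table, log = build_exposure_table(empty, schools, net, parcels)
    assert table.empty and log.empty


def test_unknown_school_id_rejected():
    net, schools, parcels = _mini_inputs()
    roster = pd.DataFrame({"pid": ["a"], "age_group": ["child"],
                           "home_x": [0.0], "home_y": [0.0],
                           "school_id": ["nope"], "trips": [5]})
    with pytest.raises(ValueError, match="unknown school"):
        build_exposure_table(roster, schools, net, parcels)


def test_distances_match_oracle_and_flags_logged():
    net, schools, parcels = _mini_inputs()
    roster = pd.DataFrame({
        "pid": ["a", "b", "c"],
        "age_group": ["child", "adolescent", "child"],
        "home_x": [0.0, 400.0, np.nan],
        "home_y": [0.0, 0.0, 100.0],
        "school_id": ["s0", "s0", "s0"],
        "trips": [10, 2, 5],
    })
    table, log = build_exposure_table(roster, schools, net, parcels)
    assert list(table["pid"]) == ["a", "b"]
    d_a = shortest_network_distance(net, (0, 0), (200, 200)) / 1000.0
    assert table.loc[table.pid == "a", "distance_km"].iloc[0] == pytest.approx(d_a)
    assert table.loc[table.pid == "a", "acs_binary"].iloc[0] == 1
    assert table.loc[table.pid == "b", "acs_binary"].iloc[0] == 0
    assert log.to_dict("records") == [{"pid": "c", "reason": "bad_address"}]


def test_grid_city_prd_between_one_and_sqrt2(big_grid):
    """Node-to-node routes on a pure grid have PRD in [1, sqrt(2)]."""
    rng = np.random.default_rng(13)
    ids = list(big_grid.nodes)
    for _ in range(40):
        a, b = rng.choice(ids, size=2, replace=False)
        pa, pb = big_grid.nodes[int(a)], big_grid.nodes[int(b)]
        e = math.dist(pa, pb)
        if e == 0:
            continue
        r = shortest_network_distance(big_grid, pa, pb) / e
        assert 1.0 - 1e-9 <= r <= math.sqrt(2) + 1e-9
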