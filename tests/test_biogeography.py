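"""Occupancy grids, spherical hull areas and range overlap/added metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleodark.biogeography import (EARTH_RADIUS_KM, hull_range,
                                    lat_range_metrics, occupancy,
                                    range_overlap_added,
                                    spherical_polygon_area)
from paleodark.occurrence import partition


# ---------------------------------------------------------------------------
# independent spherical-area oracle: Girard angle-sum excess

def _girard_area(lon, lat, radius=EARTH_RADIUS_KM):
    """Sum of interior angles minus (n-2)pi, computed from tangent vectors —
    an independent route to the spherical excess."""
    lon = np.radians(np.asarray(lon, float))
    lat = np.radians(np.asarray(lat, float))
    v = np.column_stack([np.cos(lat) * np.cos(lon),
                         np.cos(lat) * np.sin(lon), np.sin(lat)])
    n = len(v)
    total = 0.0
    for i in range(n):
        a, b, c = v[i - 1], v[i], v[(i + 1) % n]
        t1 = a - b * (b @ a)
        t2 = c - b * (b @ c)
        cosang = (t1 @ t2) / (np.linalg.norm(t1) * np.linalg.norm(t2))
        total += math.acos(np.clip(cosang, -1.0, 1.0))
    return (total - (n - 2) * math.pi) * radius ** 2


def test_two_points_area_zero():
    h = hull_range([0.0, 5.0], [0.0, 5.0])
    assert h.area_km2 == 0.0
    assert h.degenerate


def test_collinear_points_area_zero():
    h = hull_range([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
    assert h.area_km2 == 0.0
    assert h.degenerate


def test_unit_square_matches_spherical_excess_oracle():
    lon = [0.0, 1.0, 1.0, 0.0]
    lat = [0.0, 0.0, 1.0, 1.0]
    h = hull_range(lon, lat)
    oracle = _girard_area(lon, lat)
    assert h.area_km2 == pytest.approx(oracle, rel=5e-3)
    # and the planar small-angle value (R*1deg)^2 to within half a percent
    planar = (EARTH_RADIUS_KM * math.radians(1.0)) ** 2
    assert h.area_km2 == pytest.approx(planar, rel=5e-3)


def test_antimeridian_cloud_handled():
    """Points straddling the date line must not produce a globe-spanning
    hull: the 2x2-degree patch at lon 179/-179 is small."""
    h = hull_range([179.0, -179.0, 179.0, -179.0], [0.0, 0.0, 2.0, 2.0])
    assert not h.wide_span
    assert h.area_km2 < 5e5
    assert h.area_km2 == pytest.approx(
        hull_range([-1.0, 1.0, -1.0, 1.0], [0.0, 0.0, 2.0, 2.0]).area_km2,
        rel=1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_subset_hull_never_exceeds_total(case):
    rng = np.random.default_rng(case)
    n = rng.integers(3, 40)
    lon = rng.uniform(-30, 60, n)
    lat = rng.uniform(-40, 40, n)
    total = hull_range(lon, lat).area_km2
    k = rng.integers(1, n + 1)
    idx = rng.choice(n, size=k, replace=False)
    sub = hull_range(lon[idx], lat[idx]).area_km2
    assert sub <= total + 1e-6 * max(total, 1.0)


def test_polygon_area_agrees_with_oracle_random_hulls():
    rng = np.random.default_rng(7)
    for _ in range(25):
        lon = rng.uniform(-20, 20, 12)
        lat = rng.uniform(-20, 20, 12)
        h = hull_range(lon, lat)
        if h.degenerate:
            continue
        oracle = _girard_area(h.vertices[:, 0], h.vertices[:, 1])
        assert h.area_km2 == pytest.approx(oracle, rel=1e-6)


# ---------------------------------------------------------------------------
# occupancy

def test_occupancy_cell_aggregation(make_occ):
    part = partition(make_occ([
        {"genus": "Ga", "plon": 10.2, "plat": 45.7},
        {"genus": "Ga", "plon": 10.9, "plat": 45.1},
    ]))
    g = occupancy(part, resolution=1.0)
    assert len(g.cells["D"]) == 1
    assert g.cells["D"] == {(10, 45)}


def test_occupancy_unique_contributions(make_occ):
    part = partition(make_occ([
        {"genus": "Ga", "plon": 0.5, "plat": 0.5,
         "in_dark": True, "in_published": False},        # c1, dark only
        {"genus": "Ga", "plon": 1.5, "plat": 0.5,
         "in_dark": True, "in_published": False},        # c2, shared
        {"genus": "Ga", "plon": 1.5, "plat": 0.5},       # c2, published
        {"genus": "Ga", "plon": 2.5, "plat": 0.5},       # c3, published only
    ]))
    g = occupancy(part)
    assert g.unique_dark == {(0, 0)}
    assert g.unique_published == {(2, 0)}
    assert g.shared == {(1, 0)}
    assert len(g.cells["D"]) == 3


def test_occupancy_empty_dataset(make_occ):
    part = partition(make_occ([{"genus": "Ga", "plon": 0.5, "plat": 0.5}]))
    g = occupancy(part)
    assert g.cells["A"] == set()


def test_occupancy_order_invariant_and_resolution_monotone(small_partition):
    g1 = occupancy(small_partition, resolution=1.0)
    shuffled = partition(small_partition.D.sample(frac=1.0, random_state=0))
    g2 = occupancy(shuffled, resolution=1.0)
    assert g1.cells["D"] == g2.cells["D"]
    g_half = occupancy(small_partition, resolution=0.5)
    assert len(g_half.cells["D"]) >= len(g1.cells["D"])


# ---------------------------------------------------------------------------
# range overlap / added

def _two_channel_part(make_occ, dark_pts, pub_pts):
    rows = [{"genus": "Ga", "plon": x, "plat": y,
             "in_dark": True, "in_published": False} for x, y in dark_pts]
    rows += [{"genus": "Ga", "plon": x, "plat": y} for x, y in pub_pts]
    return partition(make_occ(rows))


def test_overlap_plus_added_is_100(make_occ):
    part = _two_channel_part(
        make_occ,
        dark_pts=[(0, 0), (4, 0), (4, 4), (0, 4)],
        pub_pts=[(1, 1), (3, 1), (3, 3), (1, 3)])
    tab = range_overlap_added(part)
    a = tab[tab["dataset"] == "A"].iloc[0]
    b = tab[tab["dataset"] == "B"].iloc[0]
    assert b["overlap_pct"] + a["added_pct"] == pytest.approx(100.0)
    # published square nested in the dark square: B adds nothing
    assert b["added_pct"] == pytest.approx(0.0)
    assert a["overlap_pct"] == pytest.approx(100.0)


def test_identical_subsets_full_overlap(make_occ):
    pts = [(0, 0), (2, 0), (2, 2), (0, 2)]
    rows = [{"genus": "Ga", "plon": x, "plat": y,
             "in_dark": True, "in_published": False} for x, y in pts]
    rows += [{"genus": "Ga", "plon": x, "plat": y} for x, y in pts]
    tab = range_overlap_added(partition(make_occ(rows)))
    for _, row in tab.iterrows():
        if row["dataset"] in ("A", "B"):
            assert row["overlap_pct"] == pytest.approx(100.0)
            assert row["added_pct"] == pytest.approx(0.0)


def test_degenerate_total_ranges_excluded(make_occ):
    part = partition(make_occ([{"genus": "Ga", "plon": 0.0, "plat": 0.0},
                               {"genus": "Ga", "plon": 1.0, "plat": 0.0}]))
    tab = range_overlap_added(part)
    assert tab.empty
    assert tab.attrs["n_degenerate"] == 1


# ---------------------------------------------------------------------------
# latitudinal ranges

def test_lat_width_and_midpoint(make_occ):
    part = partition(make_occ([
        {"genus": "Ga", "plat": -10.0, "plon": 0.0},
        {"genus": "Ga", "plat": 20.0, "plon": 1.0},
    ]))
    tab = lat_range_metrics(part)
    b = tab[tab["dataset"] == "B"].iloc[0]
    assert b["width_deg"] == pytest.approx(30.0)
    assert b["lat_min"] == -10.0 and b["lat_max"] == 20.0
    assert b["midpoint_shift_deg"] == pytest.approx(0.0)


def test_lat_subset_overlap_and_shift(make_occ):
    rows = [{"genus": "Ga", "plat": 0.0, "plon": 0.0,
             "in_dark": True, "in_published": False},
            {"genus": "Ga", "plat": 20.0, "plon": 0.0,
             "in_dark": True, "in_published": False},
            {"genus": "Ga", "plat": 0.0, "plon": 1.0},
            {"genus": "Ga", "plat": 10.0, "plon": 1.0}]
    part = partition(make_occ(rows))
    tab = lat_range_metrics(part)
    b = tab[tab["dataset"] == "B"].iloc[0]
    assert b["overlap_pct"] == pytest.approx(50.0)      # [0,10] in [0,20]
    assert b["midpoint_shift_deg"] == pytest.approx(-5.0)
    a = tab[tab["dataset"] == "A"].iloc[0]
    # without dark data the range halves: dark adds 50% of the total width
    assert a["width_added_pct_total"] == pytest.approx(50.0)
    assert a["width_added_pct_rest"] == pytest.approx(100.0)
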