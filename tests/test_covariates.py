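"""Distance covariates, the deforestation index, and collinearity screening."""

import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, Polygon

from ituri.covariates import (DEFAULT_PRIORITY, Landscape, collinearity_screen,
                              deforestation_change, deforestation_index,
                              distance_covariates)
from ituri.io import SamplingLocation, SurveyDataset, Transect


def square_park(side=100.0):
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


def make_ds(transects):
    locs = {}
    for t in transects:
        locs.setdefault(t.location_id, []).append(t)
    locations = [SamplingLocation(lid, ts[0].origin, tuple(x.transect_id for x in ts))
                 for lid, ts in locs.items()]
    return SurveyDataset(epoch="1995", observations=[], transects=transects,
                         locations=locations)


def test_distance_covariates_geometry_basics():
    land = Landscape(
        park_boundary=square_park(),
        roads=[LineString([(0, 50), (100, 50)])],
        villages=[Point(10, 10)],
        towns=[Point(110, 50)],
        headquarters=Point(50, 50),
    )
    # midpoint exactly at the park centroid, sitting on the road
    t_mid = Transect("T1", "L1", origin=(48.0, 50.0), bearing=90.0, length=4.0)
    # a midpoint outside the park
    t_out = Transect("T2", "L2", origin=(108.0, 50.0), bearing=90.0, length=4.0)
    tab = distance_covariates(make_ds([t_mid, t_out]), land)
    assert tab.loc["T1", "dist_road"] == pytest.approx(0.0, abs=1e-12)
    assert tab.loc["T1", "dist_boundary"] == pytest.approx(50.0)
    assert tab.loc["T1", "dist_hq"] == pytest.approx(0.0, abs=1e-12)
    assert bool(tab.loc["T1", "inside_park"])
    assert not bool(tab.loc["T2", "inside_park"])
    assert tab.loc["T2", "dist_town"] == pytest.approx(0.0, abs=1e-12)


def test_distances_match_brute_force_segment_oracle(rng):
    verts = [(rng.uniform(0, 100), rng.uniform(0, 100)) for _ in range(6)]
    road = LineString(verts)
    land = Landscape(park_boundary=square_park(), roads=[road])
    ts = [Transect(f"T{i}", f"L{i}", origin=(rng.uniform(0, 100), rng.uniform(0, 100)),
                   bearing=rng.uniform(0, 360), length=3.0) for i in range(20)]
    tab = distance_covariates(make_ds(ts), land)

    def point_segment(p, a, b):
        a, b, p = map(np.asarray, (a, b, p))
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
        return float(np.hypot(*(a + t * ab - p)))

    for t in ts:
        p = t.midpoint
        oracle = min(point_segment(p, verts[i], verts[i + 1]) for i in range(5))
        assert tab.loc[t.transect_id, "dist_road"] == pytest.approx(oracle, abs=1e-9)


def test_distance_covariates_translation_invariant(rng):
    shift = np.array([37.5, -12.25])
    land = Landscape(park_boundary=square_park(),
                     roads=[LineString([(0, 50), (100, 50)])],
                     towns=[Point(110, 60)], headquarters=Point(50, 40))
    land2 = Landscape(
        park_boundary=Polygon([(x + shift[0], y + shift[1])
                               for x, y in square_park().exterior.coords]),
        roads=[LineString([(0 + shift[0], 50 + shift[1]), (100 + shift[0], 50 + shift[1])])],
        towns=[Point(110 + shift[0], 60 + shift[1])],
        headquarters=Point(50 + shift[0], 40 + shift[1]),
    )
    ts1, ts2 = [], []
    for i in range(8):
        x, y = rng.uniform(10, 90, 2)
        ts1.append(Transect(f"T{i}", f"L{i}", (x, y), 45.0, 3.0))
        ts2.append(Transect(f"T{i}", f"L{i}", (x + shift[0], y + shift[1]), 45.0, 3.0))
    t1 = distance_covariates(make_ds(ts1), land)
    t2 = distance_covariates(make_ds(ts2), land2)
    cols = ["dist_road", "dist_town", "dist_boundary", "dist_hq"]
    pd.testing.assert_frame_equal(t1[cols], t2[cols], atol=1e-9)


def test_deforestation_change_clamps_regrowth():
    grid = pd.DataFrame({
        "cx_km": [0, 10, 20], "cy_km": [0, 0, 0], "cell_km": 10.0,
        "nonforest_t1_km2": [2.0, 5.0, 1.0],
        "nonforest_t2_km2": [5.0, 2.0, 1.0],
    })
    delta = deforestation_change(grid)
    assert list(delta) == [3.0, 0.0, 0.0]


def test_deforestation_index_formula_and_homogeneity():
    one = pd.DataFrame({"cx_km": [10.0], "cy_km": [0.0], "cell_km": [1.0],
                        "nonforest_t1_km2": [1.0], "nonforest_t2_km2": [1.0]})
    assert deforestation_index((0, 0), one) == pytest.approx(0.1)
    # doubling every distance halves the index at exponent 1
    two = one.assign(cx_km=[20.0])
    assert deforestation_index((0, 0), two) == pytest.approx(0.05)
    # exponent 2 quarters it instead
    assert deforestation_index((0, 0), two, exponent=2) == pytest.approx(
        deforestation_index((0, 0), one, exponent=2) / 4)


def test_deforestation_index_nine_cell_hand_sum():
    xs, ys = np.meshgrid([0, 10, 20], [0, 10, 20])
    areas = np.arange(1.0, 10.0)
    grid = pd.DataFrame({"cx_km": xs.ravel(), "cy_km": ys.ravel(), "cell_km": 10.0,
                         "nonforest_t1_km2": areas, "nonforest_t2_km2": areas})
    p = (-5.0, -5.0)
    oracle = sum(a / max(np.hypot(x - p[0], y - p[1]), 5.0)
                 for a, x, y in zip(areas, xs.ravel(), ys.ravel()))
    assert deforestation_index(p, grid) == pytest.approx(oracle, rel=1e-12)


def test_deforestation_index_additive_and_monotone():
    rng = np.random.default_rng(2)
    grid = pd.DataFrame({
        "cx_km": rng.uniform(0, 50, 12), "cy_km": rng.uniform(0, 50, 12),
        "cell_km": 5.0, "nonforest_t1_km2": rng.uniform(0, 20, 12),
        "nonforest_t2_km2": rng.uniform(0, 25, 12),
    })
    p = (60.0, 60.0)
    whole = deforestation_index(p, grid)
    part = (deforestation_index(p, grid.iloc[:5]) + deforestation_index(p, grid.iloc[5:]))
    assert whole == pytest.approx(part, rel=1e-12)
    bumped = grid.copy()
    bumped.loc[3, "nonforest_t1_km2"] += 1.0
    assert deforestation_index(p, bumped) > whole
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert deforestation_index(p, grid.iloc[:0]) == 0.0


def test_grid_invariants_enforced():
    bad = pd.DataFrame({"cx_km": [0.0], "cy_km": [0.0], "cell_km": [10.0],
                        "nonforest_t1_km2": [150.0], "nonforest_t2_km2": [0.0]})
    with pytest.raises(ValueError, match="cell area"):
        Landscape(park_boundary=square_park(), deforestation_grid=bad)


def test_collinearity_screen_drops_village_correlated_with_road(rng):
    road = rng.uniform(0, 50, 100)
    tab = pd.DataFrame({
        "dist_road": road,
        "dist_village": 2 * road + rng.normal(0, 1e-6, 100),
        "dist_town": rng.uniform(0, 80, 100),
    })
    retained, corr = collinearity_screen(tab)
    assert "dist_village" not in retained
    assert {"dist_road", "dist_town"} <= set(retained)
    assert abs(corr.loc["dist_road", "dist_village"]) > 0.999


def test_collinearity_screen_orthogonal_all_retained(rng):
    tab = pd.DataFrame(rng.normal(size=(200, 4)),
                       columns=["dist_road", "dist_town", "slope", "deforestation_index"])
    retained, _ = collinearity_screen(tab)
    assert len(retained) == 4


def test_collinearity_screen_matches_greedy_oracle(rng):
    cols = ["dist_road", "dist_village", "dist_town", "dist_boundary"]
    base = rng.normal(size=(120, 2))
    tab = pd.DataFrame({
        "dist_road": base[:, 0],
        "dist_village": 0.9 * base[:, 0] + 0.3 * rng.normal(size=120),
        "dist_town": base[:, 1],
        "dist_boundary": 0.8 * base[:, 1] + 0.4 * base[:, 0],
    })
    retained, _ = collinearity_screen(tab, r_max=0.6)
    # independent re-application of the stated rule in priority order
    corr = tab[cols].corr().abs()
    keep = []
    for c in [c for c in DEFAULT_PRIORITY if c in cols]:
        if all(corr.loc[c, k] < 0.6 for k in keep):
            keep.append(c)
    assert retained == keep


def test_collinearity_screen_constant_column_dropped(rng):
    tab = pd.DataFrame({"dist_road": rng.normal(size=50),
                        "slope": np.full(50, 3.0),
                        "dist_town": rng.normal(size=50)})
    with pytest.warns(UserWarning, match="constant"):
        retained, _ = collinearity_screen(tab)
    assert "slope" not in retained
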