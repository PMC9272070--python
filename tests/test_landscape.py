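"""Lattice construction, bilinear weights, neighbourhoods and LDD geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marshsim.constants import SIZE_CLIM, SIZE_HAB
from marshsim.landscape import (
    ClimateGridSpec,
    bilinear_weights,
    build_landscape,
    build_neighborhood,
    grassland_cover,
    read_landscape_csv,
    select_ldd_targets,
    write_landscape_csv,
    write_landscape_geojson,
    write_weight_table,
)
from marshsim.synthetic_data import LandscapeSpec, gen_landscape

QUAD_CENTERS = {
    "SW": (6000.0, 6000.0),
    "SE": (18000.0, 6000.0),
    "NW": (6000.0, 18000.0),
    "NE": (18000.0, 18000.0),
}


class TestBilinearWeights:
    def test_collocation_gives_full_weight(self):
        w = bilinear_weights((6000.0, 6000.0), QUAD_CENTERS)
        assert w["SW"] == pytest.approx(1.0)
        assert w["SE"] == w["NW"] == w["NE"] == 0.0

    def test_equidistant_point_splits_evenly(self):
        w = bilinear_weights((12000.0, 12000.0), QUAD_CENTERS)
        for v in w.values():
            assert v == pytest.approx(0.25)

    def test_quarter_point_closed_form(self):
        # point at (1/4, 1/4) of the inter-centre square from SW:
        # (1-u)(1-v) with u = v = 0.25
        w = bilinear_weights((9000.0, 9000.0), QUAD_CENTERS)
        assert w["SW"] == pytest.approx(0.5625)
        assert w["SE"] == pytest.approx(0.1875)
        assert w["NW"] == pytest.approx(0.1875)
        assert w["NE"] == pytest.approx(0.0625)

    def test_outside_rectangle_falls_back_to_nearest(self):
        centers = {"SW": (6000.0, 6000.0)}
        w = bilinear_weights((30001.0, 6000.0), centers)
        assert w == {"SW": 1.0}

    @given(
        x=st.floats(min_value=6000, max_value=18000),
        y=st.floats(min_value=6000, max_value=18000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_partition_of_unity_and_nonnegativity(self, x, y):
        w = bilinear_weights((x, y), QUAD_CENTERS)
        assert all(v >= 0 for v in w.values())
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)


class TestBuildLandscape:
    def test_single_climate_cell_gets_weight_one(self, single_climate_landscape):
        ls = single_climate_landscape
        for gid, entries in ls.weights.items():
            assert len(entries) == 1
            assert entries[0][2] == pytest.approx(1.0)

    def test_quad_interior_cells_map_to_four(self, quad_climate_landscape):
        ls = quad_climate_landscape
        # a cell well inside the inter-centre rectangle
        interior = [
            gid for gid, entries in ls.weights.items() if len(entries) == 4
        ]
        assert interior, "expected interior cells mapped to 4 climate cells"
        for gid in interior[:100]:
            total = sum(w for _c, _d, w in ls.weights[gid])
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_partition_of_unity_everywhere(self, quad_climate_landscape):
        for gid, entries in quad_climate_landscape.weights.items():
            assert sum(w for _c, _d, w in entries) == pytest.approx(1.0, abs=1e-12)
            assert len(entries) >= 1

    def test_two_cell_row_renormalises_to_hand_values(self):
        # 96x48 habitat under a 2x1 climate row; the point (8125, 11875)
        # lies north of both centres, so only SW/SE remain and the common
        # y-factor cancels: w = (9875/12000, 2125/12000)
        grid = np.ones((48, 96), dtype=bool)
        ls = build_landscape(grid, ClimateGridSpec(nx=2, ny=1))
        gid = int((11875 // 250) * 96 + (8125 // 250))  # centre (8125, 11875)
        assert ls.center_xy(gid) == (8125.0, 11875.0)
        w = {d: v for _c, d, v in ls.weights[gid]}
        assert w["SW"] == pytest.approx(9875 / 12000, abs=1e-12)
        assert w["SE"] == pytest.approx(2125 / 12000, abs=1e-12)

    def test_grassland_outside_climate_coverage_errors(self):
        grid = np.ones((48, 96), dtype=bool)  # 24 km wide
        with pytest.raises(ValueError, match="outside the climate lattice"):
            build_landscape(grid, ClimateGridSpec(nx=1, ny=1))


class TestGrasslandCover:
    def test_full_grassland_is_one(self, single_climate_landscape):
        assert grassland_cover(single_climate_landscape, (6000, 6000), 1500) == 1.0

    def test_no_grassland_is_zero(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[0, 0] = True
        ls = build_landscape(grid, ClimateGridSpec(nx=1, ny=1))
        # far corner: only non-grassland cells within 300 m
        assert grassland_cover(ls, (2375.0, 2375.0), 300.0) == 0.0

    def test_matches_brute_force_enumeration(self, small_random_landscape):
        ls = small_random_landscape
        center, radius = (2500.0, 2500.0), 1500.0
        n_tot = n_grass = 0
        flat = ls.is_grassland.ravel()
        for cid in range(ls.n_cells):
            cx, cy = ls.center_xy(cid)
            if math.hypot(cx - center[0], cy - center[1]) <= radius:
                n_tot += 1
                n_grass += bool(flat[cid])
        assert grassland_cover(ls, center, radius) == n_grass / n_tot

    def test_empty_radius_errors(self, single_climate_landscape):
        with pytest.raises(ValueError):
            grassland_cover(single_climate_landscape, (1e6, 1e6), 100.0)


class TestNeighborhood:
    def test_full_lattice_radius_1500_has_112_targets(self, quad_climate_landscape):
        ls = quad_climate_landscape
        source = ls.grassland_ids[len(ls.grassland_ids) // 2 + 48]  # interior
        nb = build_neighborhood(ls, int(source), 1500.0)
        # independent oracle: enumerate integer offsets
        expected = sum(
            1
            for i in range(-6, 7)
            for j in range(-6, 7)
            if (i, j) != (0, 0) and SIZE_HAB * math.hypot(i, j) <= 1500.0
        )
        assert expected == 112
        assert len(nb.in_radius) == 112

    def test_radius_250_gives_rook_neighbors(self, quad_climate_landscape):
        ls = quad_climate_landscape
        source = int(ls.grassland_ids[50 * 96 + 50])
        nb = build_neighborhood(ls, source, 250.0)
        assert len(nb.in_radius) == 4
        assert all(d == pytest.approx(250.0) for _t, d in nb.in_radius)

    def test_distances_within_radius_and_exclude_self(self, small_random_landscape):
        ls = small_random_landscape
        source = int(ls.grassland_ids[0])
        nb = build_neighborhood(ls, source, 1000.0)
        for tid, d in nb.in_radius:
            assert 0 < d <= 1000.0
            assert tid != source

    def test_symmetry_on_full_lattice(self, quad_climate_landscape):
        ls = quad_climate_landscape
        a = int(ls.grassland_ids[40 * 96 + 40])
        b = int(ls.grassland_ids[40 * 96 + 43])
        nb_a = build_neighborhood(ls, a, 1000.0)
        nb_b = build_neighborhood(ls, b, 1000.0)
        assert (b in [t for t, _ in nb_a.in_radius]) == (
            a in [t for t, _ in nb_b.in_radius]
        )

    def test_isolated_source_triggers_ldd(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[20, 20] = True
        grid[20, 0] = True  # 5000 m due west
        ls = build_landscape(grid, ClimateGridSpec(nx=1, ny=1))
        source = 20 * 40 + 20
        nb = build_neighborhood(ls, source, 1500.0)
        assert nb.in_radius == []
        assert len(nb.ldd) == 1
        tid, dist, direction = nb.ldd[0]
        assert tid == 20 * 40 + 0
        assert dist == pytest.approx(5000.0)
        assert direction == "W"


def _sector_oracle(dx, dy, azimuth):
    ang = math.degrees(math.atan2(dy, dx))
    diff = (ang - azimuth + 180.0) % 360.0 - 180.0
    return abs(diff) < 22.5


class TestLddTargets:
    def test_full_inradius_ring_yields_no_ldd(self, quad_climate_landscape):
        ls = quad_climate_landscape
        source = int(ls.grassland_ids[48 * 96 + 48])
        assert select_ldd_targets(ls, source, 1500.0) == []

    def test_single_distant_cell_due_north(self):
        grid = np.zeros((41, 41), dtype=bool)
        grid[20, 20] = True
        grid[40, 20] = True  # 5000 m due north (y grows northward)
        ls = build_landscape(grid, ClimateGridSpec(nx=1, ny=1))
        targets = select_ldd_targets(ls, 20 * 41 + 20, 1500.0)
        norths = [t for t in targets if t[2] == "N"]
        assert len(norths) == 1
        assert norths[0][0] == 40 * 41 + 20
        assert norths[0][1] == pytest.approx(5000.0)

    def test_tie_breaks_on_lowest_cell_id(self):
        # two equidistant candidates inside the N sector
        grid = np.zeros((41, 41), dtype=bool)
        grid[20, 20] = True
        grid[36, 19] = True
        grid[36, 21] = True  # same distance, both in N sector
        ls = build_landscape(grid, ClimateGridSpec(nx=1, ny=1))
        targets = select_ldd_targets(ls, 20 * 41 + 20, 1500.0)
        norths = [t for t in targets if t[2] == "N"]
        assert len(norths) == 1
        assert norths[0][0] == 36 * 41 + 19  # lower id wins

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_sector_scan(self, seed):
        habitat = gen_landscape(LandscapeSpec(nx=25, ny=25, cover=0.08, seed=seed))
        habitat[12, 12] = True
        ls = build_landscape(habitat, ClimateGridSpec(nx=1, ny=1))
        source = 12 * 25 + 12
        rad = 1500.0
        got = {d: (t, dist) for t, dist, d in select_ldd_targets(ls, source, rad)}
        sx, sy = ls.center_xy(source)
        from marshsim.landscape import DIRECTIONS

        for direction, azimuth in DIRECTIONS.items():
            in_sector = []
            for gid in ls.grassland_ids:
                gid = int(gid)
                if gid == source:
                    continue
                cx, cy = ls.center_xy(gid)
                if _sector_oracle(cx - sx, cy - sy, azimuth):
                    in_sector.append((gid, math.hypot(cx - sx, cy - sy)))
            near = [g for g, d in in_sector if d <= rad]
            far = [(g, d) for g, d in in_sector if d > rad]
            if near or not far:
                assert direction not in got
            else:
                dmin = min(d for _g, d in far)
                best = min(g for g, d in far if d == dmin)
                assert got[direction] == (best, pytest.approx(dmin))

    def test_ldd_only_for_empty_directions(self, small_random_landscape):
        ls = small_random_landscape
        from marshsim.landscape import DIRECTIONS

        for source in map(int, ls.grassland_ids[::17]):
            nb = build_neighborhood(ls, source, 1000.0)
            sx, sy = ls.center_xy(source)
            for _tid, _d, direction in nb.ldd:
                for t, _dist in nb.in_radius:
                    cx, cy = ls.center_xy(t)
                    assert not _sector_oracle(
                        cx - sx, cy - sy, DIRECTIONS[direction]
                    ), "LDD direction must have an empty in-radius sector"


class TestLandscapeIO:
    def test_csv_roundtrip(self, small_random_landscape, tmp_path):
        ls = small_random_landscape
        path = tmp_path / "landscape.csv"
        write_landscape_csv(ls, path)
        back = read_landscape_csv(path, ls.climate_spec)
        assert np.array_equal(back.is_grassland, ls.is_grassland)
        assert back.weights == ls.weights

    def test_geojson_features_are_squares(self, tmp_path):
        import json

        grid = np.zeros((4, 4), dtype=bool)
        grid[1, 2] = True
        ls = build_landscape(grid, ClimateGridSpec(nx=1, ny=1))
        path = tmp_path / "landscape.geojson"
        write_landscape_geojson(ls, path)
        with open(path) as fh:
            doc = json.load(fh)
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == 1
        ring = doc["features"][0]["geometry"]["coordinates"][0]
        assert len(ring) == 5 and ring[0] == ring[-1]

    def test_weight_table_export(self, quad_climate_landscape, tmp_path):
        import pandas as pd

        path = tmp_path / "weights.csv"
        write_weight_table(quad_climate_landscape, path)
        df = pd.read_csv(path)
        sums = df.groupby("grassland_id")["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
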