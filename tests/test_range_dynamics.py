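"""Binary matrices, change categories and conservation identities,
centroids, geodesic displacements, cosine similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichecast as nc
from nichecast.rasters import EARTH_RADIUS_KM, GridGeometry, SuitabilityRaster, cell_area_grid_km2


def _raster(values, grid=None, mask=None):
    values = np.asarray(values, dtype=float)
    grid = grid or GridGeometry(100.0, 20.0, 0.5, *values.shape)
    mask = np.zeros(values.shape, bool) if mask is None else mask
    return SuitabilityRaster(grid=grid, values=values, nodata_mask=mask)


def _random_binary_pair(seed, shape=(50, 50)):
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=shape) < 0.1
    grid = GridGeometry(100.0, 20.0, 0.25, *shape)
    out = []
    for _ in range(2):
        vals = rng.uniform(size=shape)
        vals[mask] = np.nan
        out.append(nc.binarize(_raster(vals, grid=grid, mask=mask), 0.5))
    return out


class TestBinarize:
    def test_threshold_is_strict(self):
        b = nc.binarize(_raster([[0.1, 0.10001], [0.0, 0.5]]), 0.1)
        assert b.values.tolist() == [[0, 1], [0, 1]]

    def test_all_zero_raster(self):
        b = nc.binarize(_raster(np.zeros((3, 3))))
        assert not (b.values == 1).any()

    def test_matches_per_cell_oracle_and_keeps_nodata(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(20, 20))
        mask = rng.uniform(size=(20, 20)) < 0.15
        vals[mask] = np.nan
        b = nc.binarize(_raster(vals, mask=mask), 0.1)
        assert np.array_equal(b.values[~mask], (vals[~mask] > 0.1).astype(int))
        assert np.all(b.values[mask] == -1)


class TestChangeMatrix:
    def test_no_change(self):
        cur, _ = _random_binary_pair(2)
        change = nc.change_matrix(cur, cur)
        assert change.area_km2("new") == 0.0
        assert change.area_km2("lost") == 0.0

    def test_total_colonization(self):
        grid = GridGeometry(100.0, 20.0, 0.5, 4, 4)
        cur = nc.binarize(_raster(np.zeros((4, 4)), grid=grid), 0.1)
        fut = nc.binarize(_raster(np.ones((4, 4)), grid=grid), 0.1)
        change = nc.change_matrix(cur, fut)
        total = cell_area_grid_km2(grid).sum()
        assert change.area_km2("new") == pytest.approx(total)
        assert change.area_km2("retained") == 0.0

    def test_categories_match_truth_table_enumeration(self):
        cur, fut = _random_binary_pair(3)
        change = nc.change_matrix(cur, fut)
        valid = cur.valid_mask
        for (c, f), label in {(0, 0): "unsuitable", (0, 1): "new",
                              (1, 0): "lost", (1, 1): "retained"}.items():
            cells = valid & (cur.values == c) & (fut.values == f)
            code = {"unsuitable": 0, "new": 1, "lost": 2, "retained": 3}[label]
            assert np.array_equal(change.categories == code, cells)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_identities(self, seed):
        cur, fut = _random_binary_pair(seed)
        change = nc.change_matrix(cur, fut)
        areas = cell_area_grid_km2(cur.grid)
        cur_suit = areas[cur.valid_mask & (cur.values == 1)].sum()
        fut_suit = areas[fut.valid_mask & (fut.values == 1)].sum()
        assert change.area_km2("retained") + change.area_km2("lost") == pytest.approx(
            cur_suit, rel=1e-12)
        assert change.area_km2("retained") + change.area_km2("new") == pytest.approx(
            fut_suit, rel=1e-12)

    def test_geometry_mismatch_rejected(self):
        a, _ = _random_binary_pair(4)
        b, _ = _random_binary_pair(5, shape=(40, 50))
        with pytest.raises(ValueError):
            nc.change_matrix(a, b)


class TestCentroid:
    def test_single_cell(self):
        grid = GridGeometry(100.0, 20.0, 0.5, 10, 10)
        vals = np.zeros((10, 10))
        vals[2, 7] = 1.0
        b = nc.binarize(_raster(vals, grid=grid), 0.5)
        lon, lat = nc.centroid(b)
        elon, elat = grid.cell_center(2, 7)
        assert (lon, lat) == (pytest.approx(elon), pytest.approx(elat))

    def test_equal_latitude_midpoint(self):
        grid = GridGeometry(95.0, 20.0, 1.0, 5, 20)
        vals = np.zeros((5, 20))
        r, c1 = grid.cell_index(100.5, 22.5)
        _, c2 = grid.cell_index(110.5, 22.5)
        vals[r, c1] = vals[r, c2] = 1.0
        b = nc.binarize(_raster(vals, grid=grid), 0.5)
        lon, lat = nc.centroid(b)
        assert lon == pytest.approx(105.5)

    def test_weighted_mean_oracle_across_latitudes(self):
        grid = GridGeometry(100.0, 0.0, 5.0, 8, 8)
        vals = np.zeros((8, 8))
        picks = [(0, 1), (3, 4), (6, 2), (7, 7)]
        for r, c in picks:
            vals[r, c] = 1.0
        b = nc.binarize(_raster(vals, grid=grid), 0.5)
        lon, lat = nc.centroid(b)
        areas = cell_area_grid_km2(grid)
        w = np.array([areas[r, c] for r, c in picks])
        lons, lats = zip(*[grid.cell_center(r, c) for r, c in picks])
        assert lon == pytest.approx(np.average(lons, weights=w))
        assert lat == pytest.approx(np.average(lats, weights=w))

    def test_centroid_inside_bounding_box(self):
        b, _ = _random_binary_pair(6)
        lon, lat = nc.centroid(b)
        rows, cols = np.nonzero(b.valid_mask & (b.values == 1))
        lons, lats = b.grid.cell_center(rows, cols)
        assert lons.min() <= lon <= lons.max()
        assert lats.min() <= lat <= lats.max()

    def test_empty_range_rejected(self):
        b = nc.binarize(_raster(np.zeros((4, 4))), 0.5)
        with pytest.raises(ValueError, match="centroid"):
            nc.centroid(b)


class TestDisplacement:
    def test_identity(self):
        d = nc.displacement((110.0, 30.0), (110.0, 30.0))
        assert d.distance_km == 0.0

    def test_one_degree_meridian_arc(self):
        d = nc.displacement((110.0, 30.0), (110.0, 31.0))
        expected = EARTH_RADIUS_KM * np.pi / 180
        assert d.distance_km == pytest.approx(expected, rel=1e-9)
        assert d.distance_km == pytest.approx(111.195, abs=0.001)
        assert d.north_km == pytest.approx(d.distance_km, rel=1e-9)
        assert d.east_km == pytest.approx(0.0, abs=1e-9)
        assert d.bearing_deg == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry(self):
        a, b = (105.2, 28.1), (108.9, 31.4)
        d1, d2 = nc.displacement(a, b), nc.displacement(b, a)
        assert d1.distance_km == pytest.approx(d2.distance_km, rel=1e-12)
        assert d1.east_km == pytest.approx(-d2.east_km, rel=1e-12)
        assert d1.north_km == pytest.approx(-d2.north_km, rel=1e-12)

    def test_planar_components_consistent_with_distance(self):
        d = nc.displacement((105.0, 28.0), (106.0, 29.0))
        planar = np.hypot(d.east_km, d.north_km)
        assert planar == pytest.approx(d.distance_km, rel=0.01)


class TestCosineSimilarity:
    def test_same_direction_is_one(self):
        v = (3.0, 4.0)
        assert nc.cosine_similarity(v, (6.0, 8.0)) == pytest.approx(1.0)

    def test_opposite_direction_is_minus_one(self):
        assert nc.cosine_similarity((3.0, 4.0), (-3.0, -4.0)) == pytest.approx(-1.0)

    def test_orthogonal_is_zero(self):
        assert nc.cosine_similarity((1.0, 0.0), (0.0, 1.0)) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            nc.cosine_similarity((0.0, 0.0), (1.0, 1.0))

    @given(
        e1=st.floats(-100, 100), n1=st.floats(-100, 100),
        e2=st.floats(-100, 100), n2=st.floats(-100, 100),
        s1=st.floats(0.01, 50), s2=st.floats(0.01, 50),
    )
    @settings(deadline=None, max_examples=100)
    def test_scale_invariance_and_symmetry(self, e1, n1, e2, n2, s1, s2):
        v1, v2 = np.array([e1, n1]), np.array([e2, n2])
        if np.linalg.norm(v1) < 1e-6 or np.linalg.norm(v2) < 1e-6:
            return
        c = nc.cosine_similarity(v1, v2)
        assert -1.0 <= c <= 1.0
        assert nc.cosine_similarity(v2, v1) == pytest.approx(c, abs=1e-12)
        assert nc.cosine_similarity(s1 * v1, s2 * v2) == pytest.approx(c, rel=1e-6, abs=1e-9)


def test_centroid_track_segments_consistent():
    grid = GridGeometry(100.0, 20.0, 0.5, 10, 10)
    binaries = []
    for top in (7, 5, 3):  # range marching north
        vals = np.zeros((10, 10))
        vals[top:top + 3, 4:7] = 1.0
        binaries.append(nc.binarize(_raster(vals, grid=grid), 0.5))
    track = nc.centroid_track(["current", "2050", "2070"], binaries)
    assert len(track.points) == 3 and len(track.segments) == 2
    assert (track.segments["north_km"] > 0).all()  # northward march
    planar = np.hypot(track.segments["east_km"], track.segments["north_km"])
    assert np.allclose(planar, track.segments["distance_km"], rtol=0.01)
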