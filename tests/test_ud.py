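import numpy as np
import pytest

from conftest import analytic_gaussian_ud
from spatniche.tracks import TrackSet
from spatniche.ud import (
    GridSpec,
    UtilizationDistribution,
    estimate_ud,
    export_ud_ascii,
    individual_uds,
    isopleth,
    isopleth_to_geojson,
    make_grid,
    pooled_ud,
    reference_bandwidth,
    truncate_ud,
)
from spatniche.specialization import volume_intersection


class TestReferenceBandwidth:
    def test_closed_form_unit_spread(self, rng):
        # build points with exact unit sd in both axes, n = 64
        pts = rng.normal(size=(64, 2))
        pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)
        assert reference_bandwidth(pts) == pytest.approx(64 ** (-1 / 6))

    def test_scale_homogeneity(self, rng):
        pts = rng.normal(size=(200, 2))
        assert reference_bandwidth(10 * pts) == pytest.approx(10 * reference_bandwidth(pts))

    def test_matches_independent_formula(self, rng):
        pts = rng.normal(size=(1000, 2))
        sigma = 0.5 * (np.std(pts[:, 0], ddof=1) + np.std(pts[:, 1], ddof=1))
        assert reference_bandwidth(pts) == pytest.approx(sigma * 1000 ** (-1 / 6))

    def test_degenerate_points_raise(self):
        with pytest.raises(ValueError):
            reference_bandwidth(np.ones((10, 2)))

    def test_too_few_points_raise(self, rng):
        with pytest.raises(ValueError):
            reference_bandwidth(rng.normal(size=(4, 2)))


class TestMakeGrid:
    def test_extent_padding(self):
        pts = np.array([[0.0, 10.0], [100.0, 20.0]])
        g = make_grid(pts, n_cells=100, extent_factor=0.5)
        assert g.x0 == pytest.approx(-50.0)
        assert g.x0 + g.n_cells * g.cell_size == pytest.approx(150.0)
        assert g.covers(pts)

    def test_grid_dimensions_flow_to_density(self, rng):
        pts = rng.normal(scale=100, size=(50, 2))
        g = make_grid(pts, n_cells=200)
        ud = estimate_ud(pts, 50.0, g)
        assert ud.density.shape == (200, 200)

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            make_grid(np.array([[1.0, 2.0]]))

    def test_cells_are_square(self, rng):
        g = make_grid(rng.normal(scale=(30, 300), size=(40, 2)), n_cells=64)
        assert g.cell_size > 0  # one shared cell size by construction


class TestEstimateUd:
    def test_single_point_gaussian_peak(self):
        pts = np.array([[0.0, 0.0]])
        g = GridSpec(x0=-5, y0=-5, cell_size=0.05, n_cells=200)
        ud = estimate_ud(pts, 1.0, g)
        # peak of the unit bivariate normal is 1/(2 pi)
        assert ud.density.max() == pytest.approx(1 / (2 * np.pi), rel=0.01)

    def test_normalization(self, rng):
        pts = rng.normal(scale=200, size=(80, 2))
        ud = estimate_ud(pts, reference_bandwidth(pts), make_grid(pts))
        assert ud.total_mass == pytest.approx(1.0, abs=1e-3)

    def test_matches_bruteforce_kernel_sum(self, rng):
        pts = rng.normal(scale=3.0, size=(10, 2))
        g = make_grid(pts, n_cells=20, extent_factor=0.3)
        h = 2.0
        ud = estimate_ud(pts, h, g)
        ref = np.zeros((20, 20))
        for iy, yc in enumerate(g.y_centers):
            for ix, xc in enumerate(g.x_centers):
                for px, py in pts:
                    ref[iy, ix] += np.exp(-((xc - px) ** 2 + (yc - py) ** 2) / (2 * h * h))
        ref /= len(pts) * 2 * np.pi * h * h
        ref /= ref.sum() * g.cell_area
        assert np.allclose(ud.density, ref)

    def test_invariant_to_point_order(self, rng):
        pts = rng.normal(scale=50, size=(60, 2))
        g = make_grid(pts)
        a = estimate_ud(pts, 20.0, g)
        b = estimate_ud(pts[::-1], 20.0, g)
        assert np.allclose(a.density, b.density)

    def test_translation_equivariance(self, rng):
        pts = rng.normal(scale=50, size=(60, 2))
        g = make_grid(pts, n_cells=100)
        shift = np.array([1234.5, -987.0])
        g2 = GridSpec(g.x0 + shift[0], g.y0 + shift[1], g.cell_size, g.n_cells)
        a = estimate_ud(pts, 20.0, g)
        b = estimate_ud(pts + shift, 20.0, g2)
        assert np.allclose(a.density, b.density)

    def test_nonpositive_bandwidth_raises(self, rng):
        pts = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            estimate_ud(pts, 0.0, make_grid(pts))


class TestIsopleth:
    def test_analytic_gaussian_areas(self):
        ud = analytic_gaussian_ud(sigma=100.0, n_cells=200)
        for p, expected_ha in [(95.0, np.pi * (-2 * np.log(0.05)) * 100**2 / 1e4),
                               (50.0, np.pi * (-2 * np.log(0.5)) * 100**2 / 1e4)]:
            assert isopleth(ud, p).area_ha == pytest.approx(expected_ha, rel=0.03)

    def test_uniform_ties_take_half_the_cells(self):
        g = GridSpec(0, 0, 1.0, 3)
        dens = np.full((3, 3), 1.0 / 9.0)
        ud = UtilizationDistribution(grid=g, density=dens)
        assert isopleth(ud, 50.0).cell_mask.sum() == 5  # ceil(9/2)

    def test_nested_and_monotone(self):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=120)
        r50, r95 = isopleth(ud, 50.0), isopleth(ud, 95.0)
        assert np.all(r95.cell_mask[r50.cell_mask])
        areas = [isopleth(ud, p).area_ha for p in (20, 50, 80, 95, 99)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_contained_mass_is_minimal_cover(self):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=100)
        r = isopleth(ud, 95.0)
        assert r.contained_mass >= 0.95
        # dropping the least-dense masked cell must fall below the level
        cell_masses = np.sort(ud.density[r.cell_mask]) * ud.grid.cell_area
        assert r.contained_mass - cell_masses[0] < 0.95

    def test_bad_level_raises(self):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=50)
        for p in (0, -5, 101):
            with pytest.raises(ValueError):
                isopleth(ud, p)


class TestTruncate:
    def test_p100_is_identity(self):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=80)
        assert np.allclose(truncate_ud(ud, 100.0).density, ud.density)

    def test_retained_mass_bound(self):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=150)
        t = truncate_ud(ud, 95.0)
        one_cell = ud.density.max() * ud.grid.cell_area
        assert 0.95 <= t.total_mass <= 0.95 + one_cell

    def test_idempotent(self):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=100)
        once = truncate_ud(ud, 95.0)
        twice = truncate_ud(once, 95.0)
        assert np.allclose(once.density, twice.density)


class TestPooledUd:
    def test_pools_all_points(self, two_cluster_points):
        ts = TrackSet.from_points(two_cluster_points)
        g = make_grid(ts.points(), n_cells=100)
        ud = pooled_ud(ts, g)
        assert ud.source == "population_pooled"
        assert ud.total_mass == pytest.approx(1.0, abs=1e-3)

    def test_exclusion_equals_remaining_individual(self, two_cluster_points):
        ts = TrackSet.from_points(two_cluster_points)
        g = make_grid(ts.points(), n_cells=100)
        rest = pooled_ud(ts, g, exclude_id="A")
        only_b = estimate_ud(two_cluster_points["B"],
                             reference_bandwidth(two_cluster_points["B"]), g)
        assert np.allclose(rest.density, only_b.density)
        assert rest.source == "rest_pooled"

    def test_excluding_everything_raises(self, rng):
        ts = TrackSet.from_points({"A": rng.normal(size=(50, 2))})
        g = make_grid(ts.points(), n_cells=50)
        with pytest.raises(ValueError):
            pooled_ud(ts, g, exclude_id="A")

    def test_pooled_iid_individuals_matches_single_ud(self, rng):
        # same underlying distribution: pooled UD ~ any individual's UD
        pts = {f"i{k}": rng.normal(scale=1000, size=(400, 2)) for k in range(4)}
        ts = TrackSet.from_points(pts)
        g = make_grid(ts.points(), n_cells=100)
        vi = volume_intersection(pooled_ud(ts, g), individual_uds(ts, g)["i0"])
        assert vi > 0.9


class TestExports:
    def test_ascii_grid_roundtrip(self, tmp_path, rng):
        pts = rng.normal(scale=100, size=(30, 2))
        ud = estimate_ud(pts, 50.0, make_grid(pts, n_cells=40))
        path = tmp_path / "ud.asc"
        export_ud_ascii(ud, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "ncols 40"
        data = np.loadtxt(lines[6:])[::-1]
        assert np.allclose(data, ud.density, rtol=1e-6)

    def test_isopleth_geojson(self, tmp_path):
        ud = analytic_gaussian_ud(sigma=50.0, n_cells=60)
        region = isopleth(ud, 95.0)
        gj = isopleth_to_geojson(region, ud.grid, tmp_path / "iso.geojson")
        assert gj["features"][0]["properties"]["area_ha"] == region.area_ha
        assert (tmp_path / "iso.geojson").exists()
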