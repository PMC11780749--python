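"""Polytope grids on S^2/S^3, their Voronoi geometry, pruning."""

import numpy as np
import pytest

from gridbind.rotations import rotational_distance
from gridbind.sphere_grids import (
    hyper_border_area,
    hyper_cell_volume,
    hypersphere_voronoi,
    icosahedral_grid,
    prune_to_size,
    spherical_polygon_area,
    spherical_voronoi,
    tesseract_grid,
    SphereGrid,
)

RNG = np.random.default_rng(7)


class TestIcosahedralGrid:
    @pytest.mark.parametrize("level, n", [(0, 12), (1, 42), (2, 162)])
    def test_point_counts(self, level, n):
        assert len(icosahedral_grid(level)) == n

    def test_unit_norm_and_separated(self):
        g = icosahedral_grid(1)
        assert np.allclose(np.linalg.norm(g.points, axis=1), 1.0, atol=1e-12)
        dots = np.clip(g.points @ g.points.T, -1, 1)
        np.fill_diagonal(dots, -1)
        assert np.arccos(dots.max()) > 1e-3  # minimal pairwise angle positive

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            icosahedral_grid(-1)


class TestTesseractGrid:
    def test_level0_counts(self):
        g = tesseract_grid(0)
        assert len(g.pre_truncation) == 16
        # canonical representatives derived by enumerating the 16 vertices
        # and applying the first-nonzero-positive rule: exactly half survive
        assert len(g) == 8

    def test_level1_pre_truncation_count(self):
        # oracle: the 3^4 - 1 boundary lattice points of the subdivided
        # 4-cube, projected to S^3, are pairwise distinct
        g = tesseract_grid(1)
        assert len(g.pre_truncation) == 80
        assert len(g) == 40

    def test_antipodal_closure(self):
        g = tesseract_grid(1)
        doubled = g.doubled
        for q in doubled:
            assert np.min(np.linalg.norm(doubled + q, axis=1)) < 1e-10

    def test_canonical_and_separated(self):
        g = tesseract_grid(1)
        for i, q in enumerate(g.quaternions):
            for p in g.quaternions[i + 1 :]:
                assert rotational_distance(q, p) > 1e-10

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            tesseract_grid(-1)


class TestPruning:
    def test_noop_and_subset(self):
        g = icosahedral_grid(1)
        same = prune_to_size(g, 42)
        assert np.allclose(same.points, g.points)
        pruned = prune_to_size(g, 40)
        assert len(pruned) == 40
        for p in pruned.points:
            assert np.min(np.linalg.norm(g.points - p, axis=1)) < 1e-12

    def test_deterministic(self):
        g = icosahedral_grid(2)
        a = prune_to_size(g, 80)
        b = prune_to_size(g, 80)
        assert np.array_equal(a.points, b.points)

    def test_keeps_polytope_vertices(self):
        g = icosahedral_grid(1)
        pruned = prune_to_size(g, 15)
        assert np.sum(pruned.levels == 0) == 12  # all original vertices kept

    def test_beats_random_removal(self):
        g = icosahedral_grid(1)
        pruned = prune_to_size(g, 40)

        def min_dist(points):
            dots = np.clip(points @ points.T, -1, 1)
            np.fill_diagonal(dots, 1)
            return np.arccos(dots).min()

        ours = min_dist(pruned.points)
        for trial in range(50):
            rng = np.random.default_rng(trial)
            keep = rng.choice(42, size=40, replace=False)
            assert ours >= min_dist(g.points[keep]) - 1e-12

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            prune_to_size(icosahedral_grid(0), 13)


class TestSphericalPolygonArea:
    def test_octant_triangle(self):
        assert spherical_polygon_area([np.pi / 2] * 3, 1.0) == pytest.approx(
            np.pi / 2
        )

    @pytest.mark.parametrize("theta", [0.3, 1.0, 2.0])
    def test_lune(self, theta):
        assert spherical_polygon_area([theta, theta], 1.0) == pytest.approx(
            2 * theta
        )

    def test_cube_projection_quadrilaterals(self):
        one = spherical_polygon_area([2 * np.pi / 3] * 4, 1.0)
        assert one == pytest.approx(2 * np.pi / 3)
        assert 6 * one == pytest.approx(4 * np.pi)

    def test_radius_scaling(self):
        assert spherical_polygon_area([np.pi / 2] * 3, 2.0) == pytest.approx(
            4 * np.pi / 2
        )

    def test_inconsistent_angles_rejected(self):
        with pytest.raises(ValueError):
            spherical_polygon_area([0.1, 0.1, 0.1], 1.0)


class TestSphericalVoronoi:
    def test_icosahedral_cells_congruent(self):
        sv = spherical_voronoi(icosahedral_grid(0), radius=1.0)
        assert np.allclose(sv.areas, 4 * np.pi / 12, atol=1e-10)
        assert sv.areas.sum() == pytest.approx(4 * np.pi, abs=1e-8)

    def test_total_area_conserved_at_radius(self):
        sv = spherical_voronoi(icosahedral_grid(1), radius=2.5)
        assert sv.areas.sum() == pytest.approx(4 * np.pi * 2.5**2, abs=1e-8)

    def test_octahedral_cells(self):
        points = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        grid = SphereGrid(points, np.zeros(6, dtype=int))
        sv = spherical_voronoi(grid, radius=1.0)
        assert np.allclose(sv.areas, 2 * np.pi / 3, atol=1e-10)
        for cell in range(6):
            assert len(sv.neighbors(cell)) == 4

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_areas_match_monte_carlo_assignment(self, level):
        # oracle: assign uniform sphere samples to the nearest grid point
        grid = icosahedral_grid(level)
        sv = spherical_voronoi(grid, radius=1.0)
        n = 10**6
        rng = np.random.default_rng(level)
        samples = rng.standard_normal((n, 3))
        samples /= np.linalg.norm(samples, axis=1, keepdims=True)
        owner = np.argmax(samples @ grid.points.T, axis=1)
        frac = np.bincount(owner, minlength=len(grid)) / n
        mc_areas = frac * 4 * np.pi
        se = 4 * np.pi * np.sqrt(frac * (1 - frac) / n)
        z = np.abs(mc_areas - sv.areas) / se
        # 4 SE per cell (Bonferroni across up to 162 simultaneous cells;
        # a flat 3 SE bound would fail by chance ~once per full run)
        assert z.max() <= 4.0
        assert z.mean() <= 1.5

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            spherical_voronoi(
                SphereGrid(np.eye(3), np.zeros(3, dtype=int)), radius=1.0
            )


class TestHyperBorderArea:
    def test_octant_triangle_embedded(self):
        verts = np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=float
        )
        assert hyper_border_area(verts) == pytest.approx(np.pi / 2)

    def test_invariant_under_4d_rotation(self):
        verts = np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=float
        )
        mat = np.linalg.qr(RNG.standard_normal((4, 4)))[0]
        rotated = verts @ mat.T
        assert hyper_border_area(rotated) == pytest.approx(np.pi / 2)

    def test_non_cospherical_rejected(self):
        verts = np.array(
            [
                [1, 0, 0, 0],
                [0, 1, 0, 0],
                [0, 0, 1, 0],
                [0, 0, 0, 1],  # spans all four dimensions
            ],
            dtype=float,
        )
        with pytest.raises(ValueError):
            hyper_border_area(verts)


@pytest.fixture(scope="module")
def tess16():
    return hypersphere_voronoi(tesseract_grid(0), n_samples=20000, seed=3)


class TestHypersphereVoronoi:
    def test_adjacency_symmetric_no_self(self, tess16):
        for a, b in tess16.adjacency:
            assert a < b
        assert len(set(tess16.adjacency)) == len(tess16.adjacency)

    def test_congruent_border_areas(self, tess16):
        areas = np.array(list(tess16.border_areas.values()))
        assert areas.std() < 1e-8
        assert np.all(areas > 0)

    def test_border_area_matches_interface_monte_carlo(self, tess16):
        # oracle: sample the bisecting great 2-sphere of one adjacent pair
        # directly and count the fraction owned by exactly that pair
        doubled = tess16.grid.doubled
        a, b = tess16.adjacency[0]
        normal = doubled[a] - doubled[b]
        normal /= np.linalg.norm(normal)
        basis = np.linalg.svd(normal[None])[2][1:]  # 3 vectors spanning plane
        rng = np.random.default_rng(11)
        plane = rng.standard_normal((200000, 3))
        plane /= np.linalg.norm(plane, axis=1, keepdims=True)
        points = plane @ basis  # uniform on the great 2-sphere
        owners = np.argsort(points @ doubled.T, axis=1)[:, -2:]
        hit = np.all(np.sort(owners, axis=1) == sorted((a, b)), axis=1)
        frac = hit.mean()
        mc_area = frac * 4 * np.pi
        se = 4 * np.pi * np.sqrt(frac * (1 - frac) / len(points))
        # canonical border area sums both antipodal interface copies
        pair_area = hyper_border_area(
            tess16.vertices[
                _shared_vertices(tess16, a, b)
            ]
        )
        assert abs(pair_area - mc_area) <= 3 * se

    def test_volumes_sum_to_hypersphere_area(self, tess16):
        assert tess16.volumes_doubled.sum() == pytest.approx(2 * np.pi**2)

    def test_volumes_uniform_within_binomial_error(self, tess16):
        n = 20000
        p = 1 / 16
        se = 2 * np.pi**2 * np.sqrt(p * (1 - p) / n)
        assert np.all(
            np.abs(tess16.volumes_doubled - 2 * np.pi**2 / 16) <= 3 * se
        )

    def test_volume_estimator_converges_like_sqrt_n(self):
        voronoi = hypersphere_voronoi(tesseract_grid(0), n_samples=2000, seed=0)
        stds = []
        for n in (2000, 8000):  # quadruple the sample size
            vols = np.array(
                [
                    hyper_cell_volume(voronoi, n_samples=n, seed=seed)[0]
                    for seed in range(20)
                ]
            )
            stds.append(vols.std())
        ratio = stds[0] / stds[1]
        assert 1.4 <= ratio <= 2.9  # expect ~2 for a 4x sample increase

    def test_single_cell_special_case(self):
        from gridbind.sphere_grids import HypersphereGrid

        grid = HypersphereGrid(
            np.array([[1.0, 0, 0, 0]]), np.zeros(1, dtype=int)
        )
        hv = hypersphere_voronoi(grid)
        assert hv.volumes[0] == pytest.approx(np.pi**2)
        assert hv.adjacency == []


def _shared_vertices(voronoi, a, b):
    ra, rb = set(voronoi.regions[a]), set(voronoi.regions[b])
    return np.array(sorted(ra & rb), dtype=int)
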