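"""COUE niche dynamics: PCA-env, occupancy grids, E/S/U, NBR/NSI."""

import numpy as np
import pytest

from nicheshift.niche import (
    DegenerateNicheError,
    NicheGrid,
    coue_partition,
    nbr,
    niche_breadths,
    niche_centroid_shift,
    niche_conservatism_test,
    nsi,
    occupancy_grid,
    pca_env,
    top_predictor,
)


class TestPcaEnv:
    def test_uncorrelated_variables_split_variance(self, rng):
        bg = rng.standard_normal((2000, 2))
        res = pca_env(bg, bg, bg[:5], bg[:5])
        assert np.all(np.abs(res.variance_explained - 0.5) < 0.05)

    def test_collinear_pair_loads_on_axis_one(self, rng):
        x = rng.standard_normal(500)
        bg = np.column_stack([x, 2 * x])
        res = pca_env(bg, bg, bg[:5], bg[:5])
        assert res.variance_explained[0] > 0.999

    def test_projection_centres_calibration_data(self, rng):
        a = rng.standard_normal((300, 3))
        b = rng.standard_normal((300, 3)) + 1.0
        res = pca_env(a, b, a[:5], b[:5])
        pooled = np.vstack([res.native_background, res.introduced_background])
        assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-9)

    def test_single_variable_rejected(self, rng):
        bg = rng.standard_normal((50, 1))
        with pytest.raises(ValueError):
            pca_env(bg, bg, bg, bg)


class TestOccupancyGrid:
    def test_max_z_is_one_and_uniform_is_flat(self, rng):
        bg = rng.uniform(-1, 1, (4000, 2))
        occ = rng.uniform(-1, 1, (2000, 2))  # occurrences ~ availability
        grid = occupancy_grid(occ, bg, r=100)
        assert np.isclose(grid.z.max(), 1.0)
        # availability-corrected surface ~flat over the well-sampled core
        x0, x1, y0, y1 = grid.extents
        core = grid.z[25:75, 25:75]
        assert core.std() / core.mean() < 0.5

    def test_tight_cluster_concentrates_mass(self, rng):
        bg = rng.uniform(-1, 1, (3000, 2))
        occ = rng.normal(0, 0.02, (200, 2))
        grid = occupancy_grid(occ, bg, r=100)
        x0, x1, y0, y1 = grid.extents
        xs = x0 + (np.arange(100) + 0.5) * (x1 - x0) / 100
        ys = y0 + (np.arange(100) + 0.5) * (y1 - y0) / 100
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        near = np.sqrt(xx**2 + yy**2) < 0.3
        assert grid.z[near].sum() / grid.z.sum() >= 0.9

    def test_identical_points_degenerate(self):
        occ = np.zeros((10, 2))
        bg = np.random.default_rng(0).uniform(-1, 1, (100, 2))
        with pytest.raises(DegenerateNicheError):
            occupancy_grid(occ, bg)


def _grid_from_z(z, extents=(0.0, 1.0, 0.0, 1.0)):
    z = np.asarray(z, dtype=float)
    if z.max() > 0:
        z = z / z.max()
    return NicheGrid(z=z, occupied_mask=z > 0, extents=extents)


class TestCouePartition:
    def test_identical_grids(self, rng):
        z = rng.uniform(0.1, 1.0, (40, 40))
        g = _grid_from_z(z)
        e, s, u = coue_partition(g, g)
        assert (e, s, u) == (0.0, 1.0, 0.0)

    def test_disjoint_grids(self):
        a = np.zeros((40, 40))
        b = np.zeros((40, 40))
        a[:10, :10] = 1.0
        b[30:, 30:] = 1.0
        e, s, u = coue_partition(_grid_from_z(a), _grid_from_z(b))
        assert (e, s, u) == (1.0, 0.0, 1.0)

    def test_equal_mass_extension(self):
        native = np.zeros((40, 40))
        native[0:10, 0:10] = 0.5
        introduced = native.copy()
        introduced[20:30, 20:30] = 0.5  # disjoint block of equal mass
        e, s, u = coue_partition(_grid_from_z(native), _grid_from_z(introduced))
        assert np.isclose(e, 0.5) and np.isclose(s, 0.5) and np.isclose(u, 0.0)

    def test_partition_bounds_on_random_grids(self, rng):
        for _ in range(25):
            a = rng.uniform(size=(30, 30)) * (rng.uniform(size=(30, 30)) < 0.4)
            b = rng.uniform(size=(30, 30)) * (rng.uniform(size=(30, 30)) < 0.4)
            if a.max() == 0 or b.max() == 0:
                continue
            e, s, u = coue_partition(_grid_from_z(a), _grid_from_z(b))
            assert np.isclose(e + s, 1.0)
            assert 0 <= e <= 1 and 0 <= s <= 1 and 0 <= u <= 1


class TestBreadthIndices:
    def test_identical_grids_equal_breadths(self, rng):
        z = rng.uniform(0.1, 1, (20, 20))
        g = _grid_from_z(z)
        nbn, nbi, nbs = niche_breadths(g, g)
        assert nbn == nbi == nbs
        assert nbr(nbi, nbn) == 1.0 and nsi(nbs, nbi, nbn) == 1.0

    def test_superset_double_cells(self):
        a = np.zeros((20, 20))
        a[:5, :10] = 1.0  # 50 cells
        b = a.copy()
        b[10:15, :10] = 1.0  # 100 cells, superset
        nbn, nbi, nbs = niche_breadths(_grid_from_z(a), _grid_from_z(b))
        assert np.isclose(nbr(nbi, nbn), 2.0)
        assert np.isclose(nbs, nbn)

    def test_disjoint_nsi_zero(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[:5, :5] = 1
        b[10:, 10:] = 1
        nbn, nbi, nbs = niche_breadths(_grid_from_z(a), _grid_from_z(b))
        assert nsi(nbs, nbi, nbn) == 0.0

    def test_arithmetic(self):
        assert nbr(3.0, 1.0) == 3.0
        assert nsi(1.0, 3.0, 1.0) == 0.5
        with pytest.raises(ZeroDivisionError):
            nbr(1.0, 0.0)

    def test_population_swap_symmetry(self, rng):
        a = _grid_from_z(rng.uniform(size=(25, 25)) * (rng.uniform(size=(25, 25)) < 0.5))
        b = _grid_from_z(rng.uniform(size=(25, 25)) * (rng.uniform(size=(25, 25)) < 0.5))
        nbn, nbi, nbs = niche_breadths(a, b)
        nbn2, nbi2, nbs2 = niche_breadths(b, a)
        assert np.isclose(nbr(nbi, nbn), 1.0 / nbr(nbi2, nbn2))
        assert np.isclose(nsi(nbs, nbi, nbn), nsi(nbs2, nbi2, nbn2))


class TestConservatismAndTopPredictor:
    @pytest.mark.parametrize(
        "nbr_v,nsi_v,verdict",
        [
            (1.995, 0.225, "rejected"),
            (2.290, 0.608, "supported"),
            (0.522, 0.686, "supported"),
        ],
    )
    def test_published_verdicts(self, nbr_v, nsi_v, verdict):
        assert niche_conservatism_test(nbr_v, nsi_v) == verdict

    def test_largest_axis1_loading_wins(self):
        loadings = np.array([[0.1, 0.896, 0.3], [0.9, 0.1, 0.1]])
        assert top_predictor(loadings, ["a", "b", "c"]) == "b"

    def test_tie_break_by_name(self):
        loadings = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert top_predictor(loadings, ["b", "a"]) == "a"


class TestCentroidShift:
    def test_identical_is_zero(self, rng):
        g = _grid_from_z(rng.uniform(size=(30, 30)))
        assert niche_centroid_shift(g, g) == 0.0

    def test_translation_recovered(self):
        a = np.zeros((50, 50))
        a[10:20, 20:30] = 1.0
        b = np.roll(a, 15, axis=0)  # shift along axis 1 of the PCA plane
        ga, gb = _grid_from_z(a), _grid_from_z(b)
        d = niche_centroid_shift(ga, gb)
        cell = 1.0 / 50
        assert abs(d - 15 * cell) <= cell

    def test_symmetric_niches_share_centre(self):
        a = np.zeros((40, 40))
        b = np.zeros((40, 40))
        a[10:20, 10:20] = 1.0
        b[20:30, 20:30] = 1.0
        mid_a = _grid_from_z((a + a[::-1, ::-1]) / 2)
        mid_b = _grid_from_z((b + b[::-1, ::-1]) / 2)
        assert niche_centroid_shift(mid_a, mid_b) < 1e-9
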