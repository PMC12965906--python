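import numpy as np
import pandas as pd
import pytest

import genecol as gc
from genecol.grid import ClimateGrid, read_esri_ascii, write_esri_ascii
from genecol.project import (
    SampledClimateRange,
    build_mask,
    focal_distance,
    merge_zone_level,
    nearest_unmasked,
    project_forest,
    project_tree,
)


def _grid_from_bands(**bands):
    return ClimateGrid(x0=0.0, y0=10.0, dx=1.0, dy=1.0,
                       bands={k: np.asarray(v, float) for k, v in bands.items()})


def _ranges(**rows):
    t = pd.DataFrame(rows, index=["min", "max", "sd"]).T
    return SampledClimateRange(t)


class TestGridIO:
    def test_ascii_round_trip_bit_exact(self, tmp_path, rng):
        g = _grid_from_bands(TD=rng.normal(size=(4, 5)),
                             MAT=rng.normal(size=(4, 5)))
        g.write_ascii(tmp_path / "g")
        back = ClimateGrid.read_ascii(tmp_path / "g")
        for name in g.bands:
            np.testing.assert_array_equal(back.bands[name], g.bands[name])
        assert (back.x0, back.y0, back.dx, back.dy) == (0.0, 10.0, 1.0, 1.0)

    def test_geotiff_round_trip(self, tmp_path, rng):
        g = _grid_from_bands(TD=rng.normal(size=(6, 6)))
        g.write_geotiff(tmp_path / "g.tif")
        back = ClimateGrid.read_geotiff(tmp_path / "g.tif")
        np.testing.assert_allclose(back.bands["TD"], g.bands["TD"],
                                   rtol=1e-6)
        assert back.dx == g.dx and back.y0 == g.y0

    def test_cell_lookup_from_top_left(self):
        g = _grid_from_bands(TD=np.zeros((4, 5)))
        assert g.cell_of(0.5, 9.5) == (0, 0)
        assert g.cell_of(4.5, 6.5) == (3, 4)
        with pytest.raises(ValueError):
            g.cell_of(-1.0, 9.5)

    def test_esri_ascii_nodata_becomes_nan(self, tmp_path):
        arr = np.array([[1.0, np.nan], [3.0, 4.0]])
        write_esri_ascii(tmp_path / "a.asc", arr, 0, 2, 1, 1)
        back, hdr = read_esri_ascii(tmp_path / "a.asc")
        assert np.isnan(back[0, 1])
        assert back[1, 1] == 4.0


class TestBuildMask:
    def test_value_beyond_one_sd_is_masked(self):
        g = _grid_from_bands(TD=[[10.0, 16.0]])  # max 14, sd 1 -> limit 15
        r = _ranges(TD=[4.0, 14.0, 1.0])
        mask = build_mask(g, r, k=1.0)
        assert mask.tolist() == [[True, False]]

    def test_boundary_value_unmasked(self):
        g = _grid_from_bands(TD=[[15.0, 3.0]])
        r = _ranges(TD=[4.0, 14.0, 1.0])
        mask = build_mask(g, r, k=1.0)
        assert mask.tolist() == [[True, True]]

    def test_inside_range_everywhere_unmasked(self):
        g = _grid_from_bands(TD=[[5.0, 9.0, 13.0]])
        r = _ranges(TD=[4.0, 14.0, 1.0])
        assert build_mask(g, r, k=1.0).all()

    def test_mask_monotone_in_k(self, rng):
        g = _grid_from_bands(
            TD=rng.normal(10, 5, (15, 15)), MAT=rng.normal(0, 3, (15, 15)))
        r = _ranges(TD=[8.0, 12.0, 1.0], MAT=[-1.0, 1.0, 0.5])
        m1 = build_mask(g, r, k=1.0)
        m2 = build_mask(g, r, k=2.0)
        assert (m1 <= m2).all()  # k=1 mask is a superset of k=2's masking

    def test_missing_ranged_variable_errors(self):
        g = _grid_from_bands(TD=[[1.0]])
        r = _ranges(MAT=[0.0, 1.0, 0.1])
        with pytest.raises(KeyError, match="MAT"):
            build_mask(g, r, k=1.0)

    def test_existing_nodata_stays_masked(self):
        g = _grid_from_bands(TD=[[10.0, np.nan]])
        r = _ranges(TD=[4.0, 14.0, 1.0])
        assert build_mask(g, r, k=1.0).tolist() == [[True, False]]


class _TreeSetup:
    @pytest.fixture()
    def tree_and_grid(self, rng):
        n = 30
        x = np.linspace(0, 10, n)
        Y = pd.DataFrame(
            {"PC1": np.where(x < 5, 0.0, 8.0) + rng.normal(0, .2, n)},
            index=[f"P{i}" for i in range(n)])
        preds = pd.DataFrame({"TD": x}, index=Y.index)
        model = gc.fit_zonetree(Y, preds, cp=0.01, min_node=5)
        grid = _grid_from_bands(TD=np.linspace(0, 10, 16).reshape(4, 4))
        return model, grid, preds


class TestProjectTree(_TreeSetup):
    def test_training_climate_cells_get_training_leaf(self, tree_and_grid):
        model, grid, preds = tree_and_grid
        mask = np.ones(grid.shape, bool)
        raster, legend = project_tree(model, grid, mask)
        flat_td = grid.bands["TD"].ravel()
        flat_zone = raster.ravel()
        for td, z in zip(flat_td, flat_zone):
            assert legend[str(z)] == model.assign({"TD": td})

    def test_all_masked_grid_yields_nodata(self, tree_and_grid):
        model, grid, _ = tree_and_grid
        raster, _ = project_tree(model, grid, np.zeros(grid.shape, bool))
        assert (raster == -1).all()

    def test_prefix_merge_reduces_to_primary_codes(self, rng):
        n = 60
        x = rng.uniform(0, 10, n)
        y2 = rng.uniform(0, 10, n)
        Y = pd.DataFrame({
            "PC1": np.where(x < 5, 0.0, 10.0) + rng.normal(0, .2, n),
            "PC2": np.where(y2 < 5, 0.0, 3.0) + rng.normal(0, .2, n),
        }, index=[f"P{i}" for i in range(n)])
        preds = pd.DataFrame({"TD": x, "MWMT": y2}, index=Y.index)
        model = gc.fit_zonetree(Y, preds, cp=0.005, min_node=5,
                                level_cut_points=(1, 5))
        grid = _grid_from_bands(
            TD=rng.uniform(0, 10, (6, 6)), MWMT=rng.uniform(0, 10, (6, 6)))
        mask = np.ones(grid.shape, bool)
        raster, legend = project_tree(model, grid, mask)
        merged, mlegend = merge_zone_level(raster, legend, level=1)
        assert len(mlegend) <= 3
        assert set(np.unique(merged)) <= set(int(k) for k in mlegend)

    def test_categorical_tree_requires_taxon_group(self):
        Y = pd.DataFrame({"PC1": [0.0, 0, 0, 9, 9, 9]},
                         index=[f"P{i}" for i in range(6)])
        preds = pd.DataFrame({"taxon": ["a", "a", "a", "b", "b", "b"]},
                             index=Y.index)
        model = gc.fit_zonetree(Y, preds, cp=0.0, min_node=3,
                                categorical=("taxon",))
        grid = _grid_from_bands(TD=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="taxon"):
            project_tree(model, grid, np.ones((2, 2), bool))
        raster, legend = project_tree(model, grid, np.ones((2, 2), bool),
                                      taxon_group="a")
        codes = {legend[str(v)] for v in np.unique(raster)}
        assert codes == {model.assign({"taxon": "a"})}


class TestProjectForestAndFocal:
    @pytest.fixture()
    def pc_grid(self, rng):
        study = gc.simulate_study(
            gc.SimConfig(n_populations=40, grid_shape=(10, 10)), seed=21)
        clim = study.climate[list(gc.CLIMATE_VARIABLES)]
        scores = pd.DataFrame({
            "PC1": np.where(clim["TD"] > clim["TD"].median(), 1.0, -1.0),
            "PC2": np.where(clim["MAP"] > clim["MAP"].median(), 0.5, -0.5),
        }, index=clim.index)
        models = gc.fit_axis_forests(
            scores, clim, gc.ForestParams(n_trees=50), master_seed=2)
        ranges = SampledClimateRange.from_normals(study.climate)
        mask = build_mask(study.grid, ranges, k=1.0)
        pc = project_forest(models, study.grid, mask)
        return pc, models, study

    def test_band_values_within_training_range(self, pc_grid):
        pc, models, _ = pc_grid
        for ax in pc.axes:
            vals = pc.band(ax)[pc.mask]
            m = models[ax]
            assert vals.min() >= m.y_min - 1e-9
            assert vals.max() <= m.y_max + 1e-9

    def test_identical_climate_gives_identical_vectors(self, rng):
        Y = pd.Series(rng.normal(size=40))
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        m = gc.fit_forest(Y, X, gc.ForestParams(n_trees=30), seed=0)
        g = ClimateGrid(0, 2, 1, 1, bands={
            "a": np.full((2, 2), 0.3), "b": np.full((2, 2), -.2),
            "c": np.full((2, 2), 1.1)})
        pc = project_forest({"PC1": m}, g, np.ones((2, 2), bool))
        assert len(np.unique(pc.values)) == 1

    def test_block_size_does_not_change_output(self, pc_grid):
        pc, models, study = pc_grid
        ranges = SampledClimateRange.from_normals(study.climate)
        mask = build_mask(study.grid, ranges, k=1.0)
        for bs in (1, 3, 1000):
            again = project_forest(models, study.grid, mask, block_size=bs)
            np.testing.assert_array_equal(
                np.nan_to_num(again.values), np.nan_to_num(pc.values))

    def test_focal_three_four_five(self):
        pc = gc.PCGrid(
            grid=ClimateGrid(0, 2, 1, 1, bands={"TD": np.zeros((1, 2))}),
            axes=["PC1", "PC2"],
            values=np.array([[[0.0, 3.0]], [[0.0, 4.0]]]),
            mask=np.ones((1, 2), bool))
        d = focal_distance(pc, lon=0.5, lat=1.5)
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(5.0)
        # symmetry: swap focal and query
        d2 = focal_distance(pc, lon=1.5, lat=1.5)
        assert d2[0, 0] == pytest.approx(5.0)
        assert d2[0, 1] == 0.0

    def test_focal_in_masked_cell_suggests_alternative(self):
        pc = gc.PCGrid(
            grid=ClimateGrid(0, 2, 1, 1, bands={"TD": np.zeros((1, 2))}),
            axes=["PC1"], values=np.array([[[1.0, 2.0]]]),
            mask=np.array([[False, True]]))
        with pytest.raises(ValueError, match="nearest unmasked"):
            focal_distance(pc, lon=0.5, lat=1.5)

    def test_raster_and_pointwise_distances_rank_identically(self, pc_grid):
        """Distances from the raster agree with pointwise predictions on
        the same climate vectors."""
        pc, models, study = pc_grid
        rows, cols = np.nonzero(pc.mask)
        take = slice(0, 12)
        recs = pd.DataFrame({
            v: study.grid.bands[v][rows[take], cols[take]]
            for v in models[pc.axes[0]].predictors})
        point = gc.predict_axes(models, recs).to_numpy()
        focal_vec = pc.values[:, rows[0], cols[0]]
        d_point = np.sqrt(((point - focal_vec) ** 2).sum(axis=1))
        d_raster = np.sqrt(((pc.values[:, rows[take], cols[take]]
                             - focal_vec[:, None]) ** 2).sum(axis=0))
        np.testing.assert_allclose(d_point, d_raster, atol=1e-9)

    def test_triangle_inequality_among_cells(self, pc_grid):
        pc, _, _ = pc_grid
        rows, cols = np.nonzero(pc.mask)
        v = pc.values[:, rows[:3], cols[:3]].T
        d01 = np.linalg.norm(v[0] - v[1])
        d12 = np.linalg.norm(v[1] - v[2])
        d02 = np.linalg.norm(v[0] - v[2])
        assert d02 <= d01 + d12 + 1e-12

    def test_nearest_unmasked_helper(self):
        mask = np.zeros((3, 3), bool)
        mask[2, 2] = True
        assert nearest_unmasked(mask, 0, 0) == (2, 2)
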