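"""Voxel counting, hemisphere bootstrap, masked smoothing, quantiles, predominance."""

import numpy as np
import pandas as pd
import pytest

from cpmap.density import (DensityMap, bootstrap_density, pooled_quantile_bins,
                           predominance, smooth, voxel_counts)
from cpmap.grid import VoxelGrid, build_voxel_grid
from cpmap.points import split_by_hemisphere
from cpmap.synthetic import simulate_cells

from conftest import make_cells
from oracles import brute_masked_gaussian, brute_voxel_counts


def full_grid(shape, edge_um=150.0):
    return VoxelGrid(edge_um=edge_um, origin_mm=np.zeros(3), shape=shape,
                     included=np.ones(shape, dtype=bool))


def map_from(values, grid, subtype="SST"):
    mean = np.full(grid.shape, np.nan)
    mean[grid.included] = np.asarray(values, dtype=float)[grid.included]
    return DensityMap(subtype=subtype, grid=grid, mean=mean, se=np.zeros_like(mean),
                      n_hemispheres=1, n_bootstrap=1)


class TestVoxelCounts:
    def test_three_cells_one_voxel_forced_arithmetic(self):
        grid = full_grid((2, 2, 2))
        cells = make_cells([[0.01, 0.01, 0.01]] * 3)
        counts, n_exc = voxel_counts(cells, grid)
        assert counts[0, 0, 0] == 3 and counts.sum() == 3 and n_exc == 0
        density = counts[0, 0, 0] / grid.voxel_volume_mm3
        assert density == pytest.approx(888.888, abs=0.01)

    def test_cell_on_shared_face_goes_to_higher_voxel(self):
        grid = full_grid((2, 2, 2))
        cells = make_cells([[0.150, 0.01, 0.01]])  # exactly on the face
        counts, n_exc = voxel_counts(cells, grid)
        assert counts[1, 0, 0] == 1 and counts.sum() == 1 and n_exc == 0

    def test_counts_match_per_point_oracle(self, small_atlas, small_grid, small_cfg):
        region, _, _, frame = small_atlas
        cells = simulate_cells(small_cfg, region, frame, subtypes=("SST",),
                               rng=np.random.default_rng(2))
        cells = cells.head(2000)
        counts, n_exc = voxel_counts(cells, small_grid)
        ocounts, on_exc = brute_voxel_counts(cells, small_grid)
        assert np.array_equal(counts, ocounts)
        assert n_exc == on_exc

    def test_count_conservation(self, small_atlas, small_grid, small_cfg):
        region, _, _, frame = small_atlas
        cells = simulate_cells(small_cfg, region, frame, subtypes=("PV",),
                               rng=np.random.default_rng(3))
        counts, n_exc = voxel_counts(cells, small_grid)
        assert counts[small_grid.included].sum() + n_exc == len(cells)
        assert counts[~small_grid.included].sum() == 0


class TestBootstrap:
    def test_single_hemisphere_zero_se(self):
        grid = full_grid((2, 2, 2))
        cells = {"H1": make_cells([[0.01, 0.01, 0.01]] * 5, hemisphere="H1")}
        dmap = bootstrap_density(cells, grid, n_boot=50, seed=0)
        assert np.all(dmap.se[grid.included] == 0.0)
        assert dmap.mean[0, 0, 0] == pytest.approx(5 / grid.voxel_volume_mm3)

    def test_identical_hemispheres_zero_se(self):
        grid = full_grid((2, 2, 2))
        coords = [[0.01, 0.01, 0.01], [0.2, 0.2, 0.2]]
        cells = {"H1": make_cells(coords, hemisphere="H1"),
                 "H2": make_cells(coords, hemisphere="H2", side="left")}
        dmap = bootstrap_density(cells, grid, n_boot=100, seed=1)
        assert np.allclose(dmap.se[grid.included], 0.0)

    def test_mean_matches_analytic_expectation(self):
        # E[bootstrap mean] is the plain across-hemisphere mean density
        grid = full_grid((1, 1, 1))
        per_h = {f"H{i}": make_cells([[0.05, 0.05, 0.05]] * n, hemisphere=f"H{i}")
                 for i, n in enumerate([2, 4, 6, 8])}
        n_boot = 200
        dmap = bootstrap_density(per_h, grid, n_boot=n_boot, seed=4)
        vol = grid.voxel_volume_mm3
        expect = np.mean([2, 4, 6, 8]) / vol
        # replicate SD / sqrt(n_boot) bounds the Monte-Carlo error of the mean
        mc_se = dmap.se[0, 0, 0] / np.sqrt(n_boot)
        assert abs(dmap.mean[0, 0, 0] - expect) < 3 * mc_se

    def test_seed_determinism(self):
        grid = full_grid((2, 2, 2))
        per_h = {f"H{i}": make_cells([[0.05 * i, 0.05, 0.05]], hemisphere=f"H{i}")
                 for i in range(1, 4)}
        a = bootstrap_density(per_h, grid, n_boot=100, seed=9)
        b = bootstrap_density(per_h, grid, n_boot=100, seed=9)
        assert np.array_equal(a.mean, b.mean, equal_nan=True)
        assert np.array_equal(a.se, b.se, equal_nan=True)

    def test_cell_resampling_unit(self):
        # cell-level bootstrap: within-hemisphere resampling gives positive SE
        # where hemisphere-level resampling of one hemisphere gives none
        grid = full_grid((2, 2, 2))
        coords = [[0.01, 0.01, 0.01]] * 6 + [[0.2, 0.2, 0.2]] * 6
        per_h = {"H1": make_cells(coords, hemisphere="H1")}
        hemi = bootstrap_density(per_h, grid, n_boot=100, seed=2, unit="hemisphere")
        cell = bootstrap_density(per_h, grid, n_boot=100, seed=2, unit="cell")
        assert np.all(hemi.se[grid.included] == 0)
        assert cell.se[0, 0, 0] > 0
        # expected density unchanged
        assert cell.mean[0, 0, 0] == pytest.approx(hemi.mean[0, 0, 0], rel=0.1)

    def test_invalid_n_boot(self):
        grid = full_grid((1, 1, 1))
        with pytest.raises(ValueError):
            bootstrap_density({"H": make_cells([[0, 0, 0]])}, grid, n_boot=0)


class TestSmoothing:
    def test_sigma_zero_is_identity(self):
        grid = full_grid((3, 3, 3))
        rng = np.random.default_rng(0)
        dmap = map_from(rng.uniform(size=grid.shape), grid)
        out = smooth(dmap, 0.0)
        assert np.array_equal(out.mean, dmap.mean, equal_nan=True)

    def test_constant_preserved_under_mask(self, small_grid):
        dmap = map_from(np.full(small_grid.shape, 123.0), small_grid)
        out = smooth(dmap, 0.5)
        assert np.allclose(out.mean[small_grid.included], 123.0)

    def test_matches_brute_force_kernel_sum(self):
        grid = full_grid((7, 7, 7))
        values = np.zeros(grid.shape)
        values[3, 3, 3] = 1.0
        out = smooth(map_from(values, grid), 0.5)
        expect = brute_masked_gaussian(values, grid.included, 0.5)
        assert np.allclose(out.mean, expect, equal_nan=True)

    def test_masked_brute_force_equivalence(self, small_grid):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 100, size=small_grid.shape)
        out = smooth(map_from(values, small_grid), 0.8)
        expect = brute_masked_gaussian(np.where(small_grid.included, values, 0.0),
                                       small_grid.included, 0.8)
        assert np.allclose(out.mean, expect, equal_nan=True)

    def test_negative_sigma_rejected(self):
        grid = full_grid((2, 2, 2))
        with pytest.raises(ValueError):
            smooth(map_from(np.ones(grid.shape), grid), -1.0)

    def test_nonnegativity_preserved(self, small_grid):
        rng = np.random.default_rng(6)
        out = smooth(map_from(rng.uniform(0, 10, small_grid.shape), small_grid), 1.0)
        assert np.all(out.mean[small_grid.included] >= 0)


class TestQuantileBins:
    def test_one_to_150_splits_evenly(self):
        grid = full_grid((150, 1, 1))
        values = (np.arange(150, dtype=float) + 1).reshape(-1, 1, 1)
        binning = pooled_quantile_bins([map_from(values, grid)], n_bins=15)
        bins = binning.bin_index["SST"][grid.included]
        # sort-and-slice oracle: 150 distinct values over 15 bins -> 10 each
        assert np.array_equal(np.bincount(bins, minlength=16)[1:], np.full(15, 10))

    def test_all_equal_densities_land_in_top_bin(self):
        grid = full_grid((3, 3, 3))
        binning = pooled_quantile_bins([map_from(np.full(grid.shape, 7.0), grid)])
        assert np.all(binning.bin_index["SST"][grid.included] == 15)
        assert np.allclose(binning.thresholds, 7.0)

    def test_map_maximum_in_top_bin(self):
        grid = full_grid((4, 4, 4))
        rng = np.random.default_rng(8)
        values = rng.uniform(size=grid.shape)
        binning = pooled_quantile_bins([map_from(values, grid)])
        argmax = np.unravel_index(np.argmax(values), values.shape)
        assert binning.bin_index["SST"][argmax] == 15

    def test_bins_partition_included_voxels(self, small_grid):
        rng = np.random.default_rng(9)
        maps = [map_from(rng.uniform(0, 50, small_grid.shape), small_grid, s)
                for s in ("SST", "PV")]
        binning = pooled_quantile_bins(maps)
        for s in ("SST", "PV"):
            b = binning.bin_index[s]
            assert np.all((b[small_grid.included] >= 1) & (b[small_grid.included] <= 15))
            assert np.all(b[~small_grid.included] == 0)
        assert np.all(np.diff(binning.thresholds) >= 0)

    def test_too_few_bins_rejected(self):
        grid = full_grid((2, 2, 2))
        with pytest.raises(ValueError):
            pooled_quantile_bins([map_from(np.ones(grid.shape), grid)], n_bins=1)


class TestPredominance:
    def test_argmax_assignment(self):
        grid = full_grid((1, 1, 1))
        maps = {s: map_from(np.full(grid.shape, v), grid, s)
                for s, v in [("SST", 5.0), ("PV", 9.0), ("TH", 1.0)]}
        pred = predominance(maps)
        assert pred.code_map[int(pred.labels[0, 0, 0])] == "PV"

    def test_three_way_tie_goes_to_sst_and_is_counted(self):
        grid = full_grid((1, 1, 1))
        maps = {s: map_from(np.full(grid.shape, 3.0), grid, s) for s in ("SST", "PV", "TH")}
        pred = predominance(maps)
        assert pred.code_map[int(pred.labels[0, 0, 0])] == "SST"
        assert pred.n_ties == 1

    def test_matches_per_voxel_comparison(self, small_grid):
        rng = np.random.default_rng(10)
        maps = {s: map_from(rng.uniform(0, 10, small_grid.shape), small_grid, s)
                for s in ("SST", "PV", "TH")}
        pred = predominance(maps)
        for ijk in np.argwhere(small_grid.included)[::7]:
            i, j, k = ijk
            vals = {s: maps[s].mean[i, j, k] for s in maps}
            winner = pred.code_map[int(pred.labels[i, j, k])]
            assert vals[winner] == max(vals.values())

    def test_needs_two_maps(self):
        grid = full_grid((1, 1, 1))
        with pytest.raises(ValueError):
            predominance({"SST": map_from(np.ones(grid.shape), grid)})
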