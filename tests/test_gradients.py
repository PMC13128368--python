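"""Axis profiles (150 μm slabs) and gradient mixed-model fits."""

import numpy as np
import pandas as pd
import pytest

from cpmap.gradients import (AxisProfile, collapse_axis, fit_axis_gradient,
                             fit_axis_sex_interaction)
from cpmap.grid import VoxelGrid

from conftest import make_cells


def full_grid(shape, edge_um=150.0):
    return VoxelGrid(edge_um=edge_um, origin_mm=np.zeros(3), shape=shape,
                     included=np.ones(shape, dtype=bool))


def linear_profile(slope, hemis, planes, intercept=1000.0, offsets=None, sexes=None):
    """Hand-built noise-free AxisProfile with exactly linear plane densities."""
    centers = 0.075 + 0.150 * np.arange(planes)
    rows = []
    for i, h in enumerate(hemis):
        off = 0.0 if offsets is None else offsets[i]
        sex = "F" if sexes is None else sexes[i]
        slp = slope if sexes is None or sex == "F" else slope + getattr(
            linear_profile, "male_extra", 0.0)
        for c in centers:
            rows.append((h, sex, float(c), intercept + off + slp * c))
    table = pd.DataFrame(rows, columns=["hemisphere_id", "sex", "plane_center_mm", "density"])
    summary = table.groupby("plane_center_mm", as_index=False)["density"].mean() \
        .rename(columns={"density": "mean_density"})
    summary["se_density"] = 0.0
    return AxisProfile(axis="AP", plane_centers_mm=centers, table=table,
                       plane_summary=summary, n_hemispheres=len(hemis))


class TestCollapse:
    def test_uniform_cells_give_flat_profile(self, box_region):
        # one cell at each 150 um voxel centre of a fully included 4x4x4 grid
        from cpmap.grid import build_voxel_grid

        grid = build_voxel_grid(box_region, (1,), edge_um=150.0)
        centers = grid.centers_mm
        cells = {"H1": make_cells(centers, hemisphere="H1")}
        prof = collapse_axis(cells, grid, "AP", n_boot=2, seed=0)
        dens = prof.table["density"].to_numpy()
        assert np.allclose(dens, dens[0])
        assert len(prof.plane_centers_mm) == 4

    def test_single_slab_forced_arithmetic(self, box_region):
        from cpmap.grid import build_voxel_grid

        grid = build_voxel_grid(box_region, (1,), edge_um=150.0)
        # 12 cells all within the first AP slab (16 voxels * 0.003375 mm^3)
        cells = {"H1": make_cells([[0.05, 0.1 + 0.03 * i % 0.5, 0.2]
                                   for i in range(12)], hemisphere="H1")}
        prof = collapse_axis(cells, grid, "AP", n_boot=2, seed=0)
        slab_vol = 16 * grid.voxel_volume_mm3
        first = prof.table[prof.table.plane_center_mm == prof.plane_centers_mm[0]]
        assert first["density"].iloc[0] == pytest.approx(12 / slab_vol)
        assert (prof.table[prof.table.plane_center_mm != prof.plane_centers_mm[0]]
                ["density"] == 0).all()

    def test_matches_per_slab_oracle_on_toy_atlas(self, small_atlas, small_grid, small_cfg):
        from cpmap.synthetic import simulate_cells

        region, _, _, frame = small_atlas
        cells = simulate_cells(small_cfg, region, frame, subtypes=("SST",),
                               rng=np.random.default_rng(12))
        from cpmap.points import mirror_left_to_right, split_by_hemisphere

        cells = mirror_left_to_right(cells, frame)
        by_h = split_by_hemisphere(cells)
        prof = collapse_axis(by_h, small_grid, "DV", n_boot=2, seed=0, region=region)
        # oracle: per hemisphere and DV layer, count cells in included voxels
        # and divide by the region volume inside those voxels
        rc = region.voxel_centers_mm(region.labels == 1)
        ridx = small_grid.mm_to_index(rc)
        ok = np.all((ridx >= 0) & (ridx < np.array(small_grid.shape)), axis=1)
        ridx = ridx[ok]
        in_inc = small_grid.included[ridx[:, 0], ridx[:, 1], ridx[:, 2]]
        for hid, sub in by_h.items():
            got = prof.table[prof.table.hemisphere_id == hid].set_index("plane_center_mm")
            pos = sub[["ap_mm", "ml_mm", "dv_mm"]].to_numpy()
            cidx = small_grid.mm_to_index(pos)
            okc = np.all((cidx >= 0) & (cidx < np.array(small_grid.shape)), axis=1)
            cidx = cidx[okc]
            okc2 = small_grid.included[cidx[:, 0], cidx[:, 1], cidx[:, 2]]
            cidx = cidx[okc2]
            for li, layer in enumerate(sorted(set(ridx[in_inc, 2]))):
                n_cells = int((cidx[:, 2] == layer).sum())
                vol = (ridx[in_inc, 2] == layer).sum() * region.spacing_mm ** 3
                expect = n_cells / vol
                assert got["density"].iloc[li] == pytest.approx(expect, rel=1e-9)

    def test_order_invariance(self, small_atlas, small_grid, small_cfg):
        from cpmap.synthetic import simulate_cells
        from cpmap.points import split_by_hemisphere

        region, _, _, frame = small_atlas
        cells = simulate_cells(small_cfg, region, frame, subtypes=("TH",),
                               rng=np.random.default_rng(13))
        by_h = split_by_hemisphere(cells)
        prof1 = collapse_axis(by_h, small_grid, "AP", n_boot=5, seed=1, region=region)
        shuffled = {h: t.sample(frac=1.0, random_state=0).reset_index(drop=True)
                    for h, t in by_h.items()}
        prof2 = collapse_axis(shuffled, small_grid, "AP", n_boot=5, seed=1, region=region)
        pd.testing.assert_frame_equal(prof1.table, prof2.table)

    def test_unknown_axis_rejected(self, small_grid):
        with pytest.raises(ValueError, match="axis"):
            collapse_axis({"H": make_cells([[0, 0, 0]])}, small_grid, "XY")


class TestVoxelUnit:
    def test_voxel_level_table_conserves_counts(self, small_atlas, small_grid, small_cfg):
        from cpmap.gradients import voxel_level_table
        from cpmap.points import split_by_hemisphere
        from cpmap.synthetic import simulate_cells
        from cpmap.density import voxel_counts

        region, _, _, frame = small_atlas
        cells = simulate_cells(small_cfg, region, frame, subtypes=("PV",),
                               rng=np.random.default_rng(17))
        by_h = split_by_hemisphere(cells)
        table = voxel_level_table(by_h, small_grid, "AP")
        vol = small_grid.voxel_volume_mm3
        for hid, sub in by_h.items():
            got = table[table.hemisphere_id == hid]["density"].sum() * vol
            counts, _ = voxel_counts(sub, small_grid)
            assert got == pytest.approx(counts[small_grid.included].sum())
        assert len(table) == len(by_h) * small_grid.n_included


class TestGradientFit:
    def test_noise_free_linear_trend_recovers_slope_exactly(self):
        prof = linear_profile(slope=100.0, hemis=["H1", "H2", "H3"], planes=10)
        fit = fit_axis_gradient(prof)
        assert fit.params["coordinate"] == pytest.approx(100.0, abs=1e-6)
        assert fit.sigma_u2 == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_limit_equals_ols(self):
        rng = np.random.default_rng(14)
        centers = 0.075 + 0.15 * np.arange(12)
        rows = []
        for h in ["A", "B", "C", "D"]:
            for c in centers:
                rows.append((h, "F", c, 500.0 + 80.0 * c + rng.normal(0, 30)))
        table = pd.DataFrame(rows, columns=["hemisphere_id", "sex", "plane_center_mm", "density"])
        prof = AxisProfile("AP", centers, table, table.iloc[:0], 4)
        fit = fit_axis_gradient(prof)
        import statsmodels.api as sm

        X = pd.DataFrame({"intercept": 1.0, "coordinate": table["plane_center_mm"]})
        ols = sm.OLS(table["density"], X).fit()
        # no group structure in the generator -> mixed fit collapses to OLS
        assert fit.params["coordinate"] == pytest.approx(float(ols.params["coordinate"]), rel=1e-3)

    def test_too_few_hemispheres_rejected(self):
        prof = linear_profile(slope=1.0, hemis=["H1"], planes=5)
        with pytest.raises(ValueError, match="hemispheres"):
            fit_axis_gradient(prof)


class TestSexInteraction:
    def test_simple_slope_identity(self):
        prof = linear_profile(slope=50.0, hemis=["F1", "F2", "M1", "M2"], planes=8,
                              offsets=[0, 10, -5, 5], sexes=["F", "F", "M", "M"])
        fit, slopes = fit_axis_sex_interaction(prof)
        assert slopes["beta_male"] - slopes["beta_female"] == pytest.approx(
            fit.params["coordinate:sex_M"], abs=1e-9)

    def test_null_interaction_is_small(self):
        rng = np.random.default_rng(15)
        centers = 0.075 + 0.15 * np.arange(15)
        rows = []
        for h, sex in [("F1", "F"), ("F2", "F"), ("F3", "F"),
                       ("M1", "M"), ("M2", "M"), ("M3", "M")]:
            u = rng.normal(0, 20)
            for c in centers:
                rows.append((h, sex, c, 800.0 + 60.0 * c + u + rng.normal(0, 25)))
        table = pd.DataFrame(rows, columns=["hemisphere_id", "sex", "plane_center_mm", "density"])
        prof = AxisProfile("AP", centers, table, table.iloc[:0], 6)
        fit, slopes = fit_axis_sex_interaction(prof)
        assert abs(fit.z["coordinate:sex_M"]) < 3.0

    def test_male_slope_offset_recovered(self):
        rng = np.random.default_rng(16)
        centers = 0.075 + 0.15 * np.arange(20)
        rows = []
        for h, sex in [(f"F{i}", "F") for i in range(6)] + [(f"M{i}", "M") for i in range(6)]:
            slope = 100.0 + (60.0 if sex == "M" else 0.0)
            u = rng.normal(0, 30)
            for c in centers:
                rows.append((h, sex, c, 1500.0 + slope * c + u + rng.normal(0, 40)))
        table = pd.DataFrame(rows, columns=["hemisphere_id", "sex", "plane_center_mm", "density"])
        prof = AxisProfile("AP", centers, table, table.iloc[:0], 12)
        fit, slopes = fit_axis_sex_interaction(prof)
        assert abs(slopes["interaction"] - 60.0) <= 2 * fit.se["coordinate:sex_M"]

    def test_single_sex_rejected(self):
        prof = linear_profile(slope=1.0, hemis=["H1", "H2"], planes=5)
        with pytest.raises(ValueError, match="sex"):
            fit_axis_sex_interaction(prof)
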