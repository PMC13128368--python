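"""Shared fixtures: a small toy reference space and deterministic cell tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpmap.frame import CoordinateFrame
from cpmap.grid import build_voxel_grid, chebyshev_exclude
from cpmap.synthetic import AtlasConfig, CellsConfig, SyntheticConfig, make_toy_atlas
from cpmap.volumes import LabelVolume


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A reduced reference space (fast; grid well under 20^3)."""
    return SyntheticConfig(
        atlas=AtlasConfig(semi_axes_mm=(0.9, 0.7, 0.8), spacing_um=50.0, margin_mm=0.2),
        cells=CellsConfig(baseline={"SST": 800.0, "PV": 1000.0, "TH": 600.0},
                          slopes={"SST": (0.0, 0.0, 200.0), "PV": (0.0, 0.0, -200.0),
                                  "TH": (150.0, 0.0, 0.0)},
                          hemisphere_sd=100.0, residual_sd=0.0, residual_axis=None,
                          sex_slope_offset={}, n_animals_per_sex=2),
        seed=20,
    )


@pytest.fixture(scope="session")
def small_atlas(small_cfg):
    """(region, ventricle, parcellation, frame) on the reduced space."""
    return make_toy_atlas(small_cfg)


@pytest.fixture(scope="session")
def small_grid(small_atlas):
    region, ventricle, _, _ = small_atlas
    grid = build_voxel_grid(region, (1,), edge_um=150.0)
    return chebyshev_exclude(grid, region, ventricle)


def make_cells(coords_mm, subtype="SST", hemisphere="A_R", side="right", sex="F",
               animal=None) -> pd.DataFrame:
    """Hand-built canonical cell table from an (N, 3) coordinate array."""
    coords_mm = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    return pd.DataFrame({
        "ap_mm": coords_mm[:, 0], "ml_mm": coords_mm[:, 1], "dv_mm": coords_mm[:, 2],
        "subtype": subtype, "animal_id": animal or hemisphere.rsplit("_", 1)[0],
        "hemisphere_id": hemisphere, "side": side, "sex": sex,
    })


@pytest.fixture
def box_region() -> LabelVolume:
    """A fully labeled 12^3 box at 50 μm: 0.6 mm sides, 4 grid voxels per axis at 150 μm."""
    labels = np.ones((12, 12, 12), dtype=np.int32)
    frame = CoordinateFrame(origin_mm=(0.025, 0.025, 0.025))
    return LabelVolume(labels=labels, spacing_um=50.0, frame=frame, label_map={1: "CP"})
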