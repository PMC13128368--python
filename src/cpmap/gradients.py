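"""One-dimensional axis profiles and axis-gradient mixed models.

Voxel-wise densities are collapsed into 150 μm slabs ("planes") along one
anatomical axis: per hemisphere and plane, density = cells in the plane's
included voxels / included volume of the plane. The gradient along the axis
is then the fixed slope of a random-intercept mixed model,

    density ~ coordinate + (1 | hemisphere),

fit on the per-hemisphere per-plane raw densities; slopes are in cells/mm³
per mm and summarize global directional bias, not non-monotonic structure.
Sex follow-ups add sex (treatment-coded, female reference) and its
interaction with coordinate, so the interaction coefficient is the
male-minus-female slope difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import voxel_counts
from .frame import AXIS_INDEX
from .grid import VoxelGrid
from .mixedlm import LmeFit, fit_random_intercept

log = logging.getLogger(__name__)


@dataclass
class AxisProfile:
    """Collapsed 1D density profile along one anatomical axis.

    ``table`` is tidy per-(hemisphere, plane): hemisphere_id, sex,
    plane_center_mm, density. ``plane_summary`` holds the bootstrap mean and
    SE of the across-hemisphere plane density.
    """

    axis: str
    plane_centers_mm: np.ndarray
    table: pd.DataFrame
    plane_summary: pd.DataFrame
    n_hemispheres: int


def collapse_axis(per_hemisphere_cells: dict[str, pd.DataFrame], grid: VoxelGrid,
                  axis: str, sex_by_hemisphere: dict[str, str] | None = None,
                  n_boot: int = 1000, seed: int | None = None,
                  region=None, plane_coord: str = "volume") -> AxisProfile:
    """Collapse densities into 150 μm planes along ``axis`` ("AP"/"ML"/"DV").

    Planes are the grid's voxel layers along the axis; a plane with zero
    included voxels is dropped for all hemispheres. Plane-level bootstrap
    mean/SE come from resampling hemispheres with replacement.

    When the ``region`` label volume is supplied, the slab's included volume
    is measured as the region-mask volume inside its included voxels (at the
    label raster's resolution). Analysis voxels that survive the boundary
    erosion can still straddle the region surface — the 50 μm margin is
    smaller than half the voxel edge — so the full-cube volume would dilute
    boundary planes and attenuate fitted gradients. For the same reason the
    plane coordinate defaults to the volume-weighted centroid of the slab's
    included region volume along the axis (``plane_coord="volume"``): for an
    intensity linear along the axis the expected slab density equals the
    intensity at that centroid, whereas the geometric slab centre
    (``plane_coord="center"``) misplaces the end planes at the region's caps
    and attenuates the fitted slope. Without ``region`` the geometric centre
    is used.
    """
    if axis not in AXIS_INDEX:
        raise ValueError(f"unknown axis {axis!r}; expected one of {list(AXIS_INDEX)}")
    ax = AXIS_INDEX[axis]
    other = tuple(i for i in range(3) if i != ax)

    vox_per_plane = grid.included.sum(axis=other)          # (n_layers,)
    retained = np.flatnonzero(vox_per_plane > 0)
    centers = grid.origin_mm[ax] + (retained + 0.5) * grid.edge_mm
    if region is not None:
        rc = region.voxel_centers_mm(region.mask((1,)))
        ridx = grid.mm_to_index(rc)
        inb = np.all((ridx >= 0) & (ridx < np.array(grid.shape)), axis=1)
        rc, ridx = rc[inb], ridx[inb]
        in_inc = grid.included[ridx[:, 0], ridx[:, 1], ridx[:, 2]]
        layer = ridx[in_inc, ax]
        rvox_per_plane = np.bincount(layer, minlength=grid.shape[ax])
        vol_per_plane = rvox_per_plane[retained] * region.spacing_mm ** 3
        if plane_coord == "volume":
            coord_sum = np.bincount(layer, weights=rc[in_inc, ax], minlength=grid.shape[ax])
            centers = coord_sum[retained] / rvox_per_plane[retained]
        elif plane_coord != "center":
            raise ValueError(f"plane_coord must be volume|center, got {plane_coord!r}")
    else:
        vol_per_plane = vox_per_plane[retained] * grid.voxel_volume_mm3

    hids = sorted(per_hemisphere_cells)
    dens = np.empty((len(hids), len(retained)))
    for r, hid in enumerate(hids):
        counts, _ = voxel_counts(per_hemisphere_cells[hid], grid)
        plane_counts = counts.sum(axis=other)[retained]
        dens[r] = plane_counts / vol_per_plane

    rows = []
    for r, hid in enumerate(hids):
        sex = (sex_by_hemisphere or {}).get(hid,
              per_hemisphere_cells[hid]["sex"].iloc[0] if len(per_hemisphere_cells[hid]) else "F")
        for c, d in zip(centers, dens[r]):
            rows.append((hid, sex, float(c), float(d)))
    table = pd.DataFrame(rows, columns=["hemisphere_id", "sex", "plane_center_mm", "density"])

    rng = np.random.default_rng(seed)
    n_h = len(hids)
    weights = rng.multinomial(n_h, np.full(n_h, 1.0 / n_h), size=n_boot)
    reps = (weights @ dens) / n_h                          # (n_boot, n_planes)
    summary = pd.DataFrame({
        "plane_center_mm": centers,
        "mean_density": reps.mean(axis=0),
        "se_density": reps.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(len(centers)),
        "included_volume_mm3": vol_per_plane,
    })
    return AxisProfile(axis=axis, plane_centers_mm=centers, table=table,
                       plane_summary=summary, n_hemispheres=n_h)


def fit_axis_gradient(profile: AxisProfile, method: str = "ML") -> LmeFit:
    """density ~ coordinate + (1 | hemisphere) on raw per-plane densities."""
    t = profile.table
    if t["hemisphere_id"].nunique() < 2:
        raise ValueError("axis-gradient fit needs at least 2 hemispheres")
    if len(profile.plane_centers_mm) < 3:
        raise ValueError("axis-gradient fit needs at least 3 planes")
    X = pd.DataFrame({"intercept": 1.0, "coordinate": t["plane_center_mm"].to_numpy()})
    return fit_random_intercept(t["density"].to_numpy(), X, t["hemisphere_id"].to_numpy(),
                                method=method)


def fit_axis_sex_interaction(profile: AxisProfile, method: str = "ML") -> tuple[LmeFit, dict]:
    """density ~ coordinate * sex + (1 | hemisphere); female is the reference.

    Returns the fit plus the per-sex simple slopes: beta_female is the
    coordinate coefficient, beta_male adds the interaction.
    """
    t = profile.table
    sexes = set(t["sex"].unique())
    if not {"M", "F"} <= sexes:
        raise ValueError(f"sex-interaction fit needs both sexes, got {sorted(sexes)}")
    male = (t["sex"] == "M").astype(float).to_numpy()
    coord = t["plane_center_mm"].to_numpy()
    X = pd.DataFrame({
        "intercept": 1.0,
        "coordinate": coord,
        "sex_M": male,
        "coordinate:sex_M": coord * male,
    })
    fit = fit_random_intercept(t["density"].to_numpy(), X, t["hemisphere_id"].to_numpy(),
                               method=method)
    slopes = {
        "beta_female": fit.params["coordinate"],
        "beta_male": fit.params["coordinate"] + fit.params["coordinate:sex_M"],
        "interaction": fit.params["coordinate:sex_M"],
        "interaction_p": fit.p["coordinate:sex_M"],
    }
    return fit, slopes


def voxel_level_table(per_hemisphere_cells: dict[str, pd.DataFrame], grid: VoxelGrid,
                      axis: str, sex_by_hemisphere: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-(hemisphere, voxel) densities with the voxel's axis coordinate.

    The alternative observational unit for the gradient model (switchable
    via the models config ``lme_unit: voxel``).
    """
    ax = AXIS_INDEX[axis]
    idx = np.argwhere(grid.included)
    coords = grid.origin_mm[ax] + (idx[:, ax] + 0.5) * grid.edge_mm
    vol = grid.voxel_volume_mm3
    frames = []
    for hid in sorted(per_hemisphere_cells):
        counts, _ = voxel_counts(per_hemisphere_cells[hid], grid)
        sex = (sex_by_hemisphere or {}).get(hid,
              per_hemisphere_cells[hid]["sex"].iloc[0] if len(per_hemisphere_cells[hid]) else "F")
        frames.append(pd.DataFrame({
            "hemisphere_id": hid, "sex": sex, "plane_center_mm": coords,
            "density": counts[grid.included] / vol,
        }))
    return pd.concat(frames, ignore_index=True)


def fit_gradient_table(table: pd.DataFrame, method: str = "ML") -> LmeFit:
    """Gradient fit on a prebuilt tidy (hemisphere, coordinate, density) table."""
    X = pd.DataFrame({"intercept": 1.0, "coordinate": table["plane_center_mm"].to_numpy()})
    return fit_random_intercept(table["density"].to_numpy(), X,
                                table["hemisphere_id"].to_numpy(), method=method)
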