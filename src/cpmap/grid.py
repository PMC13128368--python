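"""The 150 μm analysis lattice over the region of interest.

The caudoputamen is partitioned into cubic analysis voxels (default edge
150 μm). A voxel is a candidate for analysis if it overlaps the region mask;
candidates are then eroded away from the region boundary and the ventricular
surface using Chebyshev (L-infinity) distances, because PV-positive ependymal
cells line the ventricle and partial-volume voxels at the boundary understate
density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import LabelVolume

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class VoxelGrid:
    """Cubic analysis lattice spanning the region bounding box.

    ``origin_mm`` is the low corner of grid voxel (0,0,0) in frame mm
    coordinates; ``included`` flags voxels that survive masking/exclusion.
    Grid axes follow the frame's (AP, ML, DV) mm axes with +1 direction.
    """

    edge_um: float
    origin_mm: np.ndarray
    shape: tuple[int, int, int]
    included: np.ndarray

    def __post_init__(self) -> None:
        if not self.edge_um > 0:
            raise ValueError("edge_um must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != tuple(self.shape):
            raise ValueError("included raster does not match grid shape")

    @property
    def edge_mm(self) -> float:
        return self.edge_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.edge_mm ** 3

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def centers_mm(self) -> np.ndarray:
        """(n_included, 3) mm centres of included voxels (index order)."""
        idx = np.argwhere(self.included)
        return self.origin_mm + (idx + 0.5) * self.edge_mm

    def index_to_mm(self, index) -> np.ndarray:
        """Centre of grid voxel(s) ``index`` in mm."""
        index = np.asarray(index)
        if np.any(index < 0) or np.any(index >= np.array(self.shape)):
            raise IndexError(f"grid index {index} outside shape {self.shape}")
        return self.origin_mm + (np.asarray(index, dtype=float) + 0.5) * self.edge_mm

    def mm_to_index(self, mm) -> np.ndarray:
        """Grid voxel containing mm point(s); half-open [low, high) intervals."""
        mm = np.asarray(mm, dtype=float)
        return np.floor((mm - self.origin_mm) / self.edge_mm + _EPS).astype(np.int64)


def build_voxel_grid(region: LabelVolume, region_labels, edge_um: float = 150.0) -> VoxelGrid:
    """Build the candidate analysis grid over a region mask.

    The grid spans the mask's bounding box, its origin anchored at the
    bounding-box minimum corner (snapped to the raster). A voxel is
    candidate-included iff at least one region-raster voxel centre of a
    listed label falls inside it.
    """
    mask = region.mask(region_labels)
    if not mask.any():
        raise ValueError(f"region labels {region_labels} select no raster voxels")
    centers = region.voxel_centers_mm(mask)
    half = region.spacing_mm / 2.0
    origin = centers.min(axis=0) - half
    upper = centers.max(axis=0) + half
    edge_mm = edge_um / 1000.0
    shape = tuple(int(np.ceil(v)) for v in ((upper - origin) / edge_mm - _EPS))

    idx = np.floor((centers - origin) / edge_mm + _EPS).astype(np.int64)
    idx = np.minimum(idx, np.array(shape) - 1)  # guard float edge of last voxel
    included = np.zeros(shape, dtype=bool)
    included[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    log.info("voxel grid: shape=%s edge=%g um, %d candidate voxels",
             shape, edge_um, int(included.sum()))
    return VoxelGrid(edge_um=edge_um, origin_mm=origin, shape=shape, included=included)


def _boundary_shell_centers(region: LabelVolume, mask: np.ndarray,
                            reach_um: float) -> np.ndarray:
    """mm centres of region-exterior raster voxels within ``reach_um`` (L∞)."""
    n_iter = int(np.ceil(reach_um / region.spacing_um)) + 1
    struct = np.ones((3, 3, 3), dtype=bool)  # Chebyshev unit ball
    dilated = ndimage.binary_dilation(mask, structure=struct, iterations=n_iter)
    shell = dilated & ~mask
    return region.voxel_centers_mm(shell)


def chebyshev_exclude(grid: VoxelGrid, region: LabelVolume,
                      ventricle: LabelVolume | None = None,
                      region_labels=(1,), ventricle_labels=(1,),
                      d_boundary_um: float = 50.0,
                      d_ventricle_um: float = 175.0) -> VoxelGrid:
    """Drop candidate voxels too close to the region boundary or ventricle.

    A candidate voxel is excluded iff the Chebyshev distance from its centre
    to the nearest region-exterior raster voxel centre is < ``d_boundary_um``,
    or to the nearest ventricle-labeled raster voxel centre is
    < ``d_ventricle_um``. Distances are centre-to-centre at the label
    raster's native resolution. Returns a new grid.
    """
    if d_boundary_um < 0 or d_ventricle_um < 0:
        raise ValueError("distance thresholds must be non-negative")
    centers = grid.centers_mm
    keep = np.ones(len(centers), dtype=bool)

    if d_boundary_um > 0:
        mask = region.mask(region_labels)
        reach = d_boundary_um + grid.edge_um / 2.0 + region.spacing_um
        shell = _boundary_shell_centers(region, mask, reach)
        if len(shell):
            dist_mm, _ = cKDTree(shell).query(centers, p=np.inf)
            keep &= dist_mm * 1000.0 >= d_boundary_um - _EPS

    if ventricle is not None and d_ventricle_um > 0:
        if ventricle.frame != region.frame:
            raise ValueError("ventricle volume is on a different coordinate frame")
        vmask = ventricle.mask(ventricle_labels)
        if vmask.any():
            vcenters = ventricle.voxel_centers_mm(vmask)
            dist_mm, _ = cKDTree(vcenters).query(centers, p=np.inf)
            keep &= dist_mm * 1000.0 >= d_ventricle_um - _EPS
    elif ventricle is None and d_ventricle_um > 0:
        log.warning("no ventricle volume supplied; ventricle exclusion skipped")

    included = np.zeros(grid.shape, dtype=bool)
    idx = np.argwhere(grid.included)[keep]
    included[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    log.info("chebyshev exclusion: %d -> %d voxels (boundary<%g um, ventricle<%g um)",
             grid.n_included, int(included.sum()), d_boundary_um, d_ventricle_um)
    return replace(grid, included=included)
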