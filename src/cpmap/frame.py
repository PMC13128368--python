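"""Physical coordinate frame of the reference space.

All analysis happens in bregma-relative millimetre coordinates on three
anatomical axes in the fixed order (AP, ML, DV): anteroposterior (increasing
anterior by default convention, sign configurable), mediolateral (increasing
lateral from the midsagittal plane), and dorsoventral (increasing ventral).
A :class:`CoordinateFrame` maps integer raster indices of a label volume to
these mm coordinates via an axis-aligned affine: ``mm = origin + sign * index
* spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXES = ("AP", "ML", "DV")
AXIS_INDEX = {name: i for i, name in enumerate(AXES)}


@dataclass(frozen=True)
class CoordinateFrame:
    """Affine placement of a raster in bregma-relative mm coordinates.

    Parameters
    ----------
    origin_mm:
        mm position, on the (AP, ML, DV) axes, of raster index (0, 0, 0)
        (the centre of the first raster voxel).
    axis_signs:
        +1 or -1 per axis: the direction in which the raster index increases
        relative to the anatomical axis. The common reference-space storage
        order runs anterior->posterior, so its AP sign is -1.
    midline_ml_mm:
        ML coordinate of the midsagittal plane, used for hemisphere mirroring.
    """

    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_signs: tuple[int, int, int] = (1, 1, 1)
    midline_ml_mm: float = 0.0

    def __post_init__(self) -> None:
        if any(s not in (-1, 1) for s in self.axis_signs):
            raise ValueError(f"axis_signs must be +/-1, got {self.axis_signs}")
        if not np.isfinite(self.midline_ml_mm):
            raise ValueError("midline_ml_mm must be finite")

    def index_to_mm(self, index, spacing_mm: float) -> np.ndarray:
        """mm coordinates of raster voxel centre(s) ``index`` (shape (..., 3))."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin_mm) + np.asarray(self.axis_signs) * index * spacing_mm

    def mm_to_index(self, mm, spacing_mm: float) -> np.ndarray:
        """Integer raster index of the voxel containing mm position(s).

        The voxel at index i owns the half-open slab
        [centre - spacing/2, centre + spacing/2) along each axis, so points
        exactly between two voxels go to the higher index.
        """
        mm = np.asarray(mm, dtype=float)
        t = np.asarray(self.axis_signs) * (mm - np.asarray(self.origin_mm)) / spacing_mm
        return np.floor(t + 0.5).astype(np.int64)

    @classmethod
    def from_dict(cls, d: dict) -> "CoordinateFrame":
        return cls(
            origin_mm=tuple(d.get("origin_mm", (0.0, 0.0, 0.0))),
            axis_signs=tuple(d.get("axis_signs", (1, 1, 1))),
            midline_ml_mm=float(d.get("midline_ml_mm", 0.0)),
        )

    def to_dict(self) -> dict:
        return {
            "origin_mm": [float(v) for v in self.origin_mm],
            "axis_signs": [int(v) for v in self.axis_signs],
            "midline_ml_mm": float(self.midline_ml_mm),
        }


#: Default frame for real reference-space (CCF-registered) data, mm units:
#: bregma sits +5.40 mm anterior of the raster AP origin, the midline at
#: ML = 5.70 mm; the stored AP axis runs anterior->posterior (sign -1).
DEFAULT_CCF_FRAME = CoordinateFrame(
    origin_mm=(5.40, -5.70, 0.0),
    axis_signs=(-1, 1, 1),
    midline_ml_mm=0.0,
)
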