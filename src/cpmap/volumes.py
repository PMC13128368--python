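"""Label volumes: integer 3D rasters in a common reference space."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nrrd_io
from .frame import CoordinateFrame

log = logging.getLogger(__name__)


@dataclass
class LabelVolume:
    """An integer 3D raster (region labels, parcel IDs) with physical placement.

    ``labels`` is indexed (AP, ML, DV); ``spacing_um`` is the isotropic raster
    voxel edge; ``frame`` maps indices to bregma-relative mm; ``label_map``
    names the integer labels that carry meaning (0 = background).
    """

    labels: np.ndarray
    spacing_um: float
    frame: CoordinateFrame
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label raster must be 3D, got shape {self.labels.shape}")
        if self.labels.size == 0:
            raise ValueError("label raster is empty")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label raster must be integer, got dtype {self.labels.dtype}")
        if not (np.isfinite(self.spacing_um) and self.spacing_um > 0):
            raise ValueError(f"spacing_um must be positive, got {self.spacing_um}")

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    def mask(self, labels: set[int] | list[int] | tuple[int, ...]) -> np.ndarray:
        """Boolean raster of voxels carrying any of the given labels."""
        labels = list(labels)
        if not labels:
            raise ValueError("empty label set")
        missing = [l for l in labels if self.label_map and l not in self.label_map]
        if missing:
            raise KeyError(f"labels {missing} not in label_map {self.label_map}")
        return np.isin(self.labels, labels)

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """(N, 3) mm coordinates of the centres of masked raster voxels."""
        idx = np.argwhere(mask)
        return self.frame.index_to_mm(idx, self.spacing_mm)

    def labels_at_mm(self, points_mm: np.ndarray, outside: int = 0) -> np.ndarray:
        """Label under each mm point; ``outside`` for points off the raster."""
        points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = self.frame.mm_to_index(points_mm, self.spacing_mm)
        inside = np.all((idx >= 0) & (idx < np.array(self.labels.shape)), axis=1)
        out = np.full(len(points_mm), outside, dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def load_label_volume(path: str | Path, frame: CoordinateFrame,
                      format: str | None = None,
                      label_map: dict[int, str] | None = None) -> LabelVolume:
    """Load a label volume from NRRD or NIfTI-1.

    ``format`` is inferred from the file extension when omitted. Spacing is
    read from the header (NRRD ``spacings``/``space directions`` interpreted
    as μm for values > 1, else mm; NIfTI zooms interpreted per its xyzt_units,
    defaulting to mm) and must be isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        name = path.name.lower()
        if name.endswith(".nrrd"):
            format = "nrrd"
        elif name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format=")

    if format == "nrrd":
        data, header = nrrd_io.read(path)
        spacings = header.get("spacings")
        if spacings is None:
            raise nrrd_io.NrrdFormatError(f"{path}: no spacings in header")
        spacings = np.asarray(spacings, dtype=float)
        # headers written in mm carry sub-unit spacings; ours are in μm
        spacing_um = float(spacings[0]) if spacings[0] > 1 else float(spacings[0]) * 1000.0
    elif format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        unit = img.header.get_xyzt_units()[0]
        to_um = {"micron": 1.0, "mm": 1000.0, "meter": 1e6, "unknown": 1000.0}[unit]
        spacings = zooms * to_um
        spacing_um = float(spacings[0])
    else:
        raise ValueError(f"unknown format {format!r}")

    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D raster, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise ValueError(f"{path}: non-integer label data")
    if not np.allclose(spacings, spacings[0]):
        raise ValueError(f"{path}: anisotropic spacing {spacings} unsupported")

    return LabelVolume(labels=np.ascontiguousarray(data), spacing_um=spacing_um,
                       frame=frame, label_map=label_map or {})


def save_label_volume(path: str | Path, volume: LabelVolume, format: str | None = None) -> None:
    """Write a label volume as NRRD (spacings in μm) or NIfTI-1 (zooms in mm)."""
    path = Path(path)
    if format is None:
        format = "nifti" if path.name.lower().endswith((".nii", ".nii.gz")) else "nrrd"
    if format == "nrrd":
        nrrd_io.write(path, volume.labels.astype(np.int32),
                      spacings=[volume.spacing_um] * 3, encoding="gzip")
    elif format == "nifti":
        import nibabel as nib

        affine = np.diag([volume.spacing_mm] * 3 + [1.0])
        img = nib.Nifti1Image(volume.labels.astype(np.int32), affine)
        img.header.set_zooms((volume.spacing_mm,) * 3)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
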