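"""Per-cell coordinate tables: reading, validation, region filtering, mirroring.

A cell table holds one row per detected soma with bregma-relative mm
coordinates (ap_mm, ml_mm, dv_mm), the interneuron subtype (SST, PV or TH),
and the sampling-unit metadata: animal, hemisphere (the independent
observational unit), side, and sex. Left-hemisphere detections are reflected
across the midsagittal plane into right-hemisphere space before any density
estimation, so both hemispheres contribute to one bilateral atlas while the
side label is preserved for lateralization questions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .frame import CoordinateFrame
from .volumes import LabelVolume

log = logging.getLogger(__name__)

SUBTYPES = ("SST", "PV", "TH")
SIDES = ("left", "right")
SEXES = ("M", "F")

CANONICAL_COLUMNS = ["ap_mm", "ml_mm", "dv_mm", "subtype", "animal_id",
                     "hemisphere_id", "side", "sex"]
COORD_COLUMNS = ["ap_mm", "ml_mm", "dv_mm"]


class SchemaError(ValueError):
    """A cell CSV does not match the declared column schema."""


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check table invariants; returns the table for chaining."""
    missing = [c for c in CANONICAL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing columns {missing}")
    coords = cells[COORD_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"{np.sum(~np.isfinite(coords).all(axis=1))} rows have missing coordinates")
    bad_subtype = set(cells["subtype"].unique()) - set(SUBTYPES)
    if bad_subtype:
        raise ValueError(f"unknown subtypes {sorted(bad_subtype)}")
    bad_side = set(cells["side"].unique()) - set(SIDES)
    if bad_side:
        raise ValueError(f"unknown side labels {sorted(bad_side)}")
    bad_sex = set(cells["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels {sorted(bad_sex)}")
    units = cells.groupby("hemisphere_id")[["animal_id", "side"]].nunique()
    inconsistent = units[(units > 1).any(axis=1)]
    if len(inconsistent):
        raise ValueError(f"hemisphere_id not unique per (animal, side): {list(inconsistent.index)}")
    return cells


def read_cells(path: str | Path, schema: dict | None = None,
               on_bad_rows: str = "error") -> pd.DataFrame:
    """Read a per-cell CSV into canonical form.

    ``schema`` may carry a ``columns`` mapping (canonical name -> CSV column)
    and ``units`` ("mm", the default, or "um"; μm coordinates are divided by
    1000). ``on_bad_rows`` controls rows with unparseable coordinates:
    "error" raises, "drop" removes them and logs the count.
    """
    schema = schema or {}
    colmap = schema.get("columns", {})
    df = pd.read_csv(path)
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"{path}: no column {src!r} for field {canon!r}")
        rename[src] = canon
    df = df.rename(columns=rename)[CANONICAL_COLUMNS].copy()

    for col in COORD_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ~np.isfinite(df[COORD_COLUMNS].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        if on_bad_rows == "drop":
            log.warning("%s: dropped %d rows with unparseable coordinates", path, int(bad.sum()))
            df = df.loc[~bad].reset_index(drop=True)
        else:
            raise ValueError(f"{path}: {int(bad.sum())} rows have unparseable coordinates")

    if schema.get("units", "mm") == "um":
        df[COORD_COLUMNS] = df[COORD_COLUMNS] / 1000.0
    for col in ("subtype", "animal_id", "hemisphere_id", "side", "sex"):
        df[col] = df[col].astype(str)
    return validate_cells(df)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical cell CSV (fixed float format for reproducible bytes)."""
    cells[CANONICAL_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def filter_to_region(cells: pd.DataFrame, region: LabelVolume,
                     region_labels=(1,)) -> pd.DataFrame:
    """Keep only cells whose containing raster voxel carries a region label."""
    labels = region.labels_at_mm(cells[COORD_COLUMNS].to_numpy(dtype=float))
    keep = np.isin(labels, list(region_labels))
    removed = int((~keep).sum())
    if removed:
        log.info("region filter: removed %d / %d cells outside the region", removed, len(cells))
    return cells.loc[keep].reset_index(drop=True)


def mirror_left_to_right(cells: pd.DataFrame, frame: CoordinateFrame) -> pd.DataFrame:
    """Reflect left-hemisphere cells across the midline; an involution.

    ``ml_mm`` of rows with side == "left" becomes ``2*midline - ml_mm``; the
    side label is kept so hemisphere identity survives pooling. Cells lying
    exactly on the midline map to themselves.
    """
    if "side" not in cells.columns or cells["side"].isna().any():
        raise ValueError("side labels are required for mirroring")
    out = cells.copy()
    left = out["side"] == "left"
    out.loc[left, "ml_mm"] = 2.0 * frame.midline_ml_mm - out.loc[left, "ml_mm"]
    log.info("mirrored %d left-hemisphere cells across ML=%g mm",
             int(left.sum()), frame.midline_ml_mm)
    return out


def split_by_hemisphere(cells: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Hemisphere-level observations: one table per hemisphere_id."""
    return {hid: sub.reset_index(drop=True) for hid, sub in cells.groupby("hemisphere_id", sort=True)}


def sex_by_hemisphere(cells: pd.DataFrame) -> dict[str, str]:
    return cells.groupby("hemisphere_id", sort=True)["sex"].first().to_dict()
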