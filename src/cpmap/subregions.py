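"""Subregion composition: parcel assignment, densities, Sidak-corrected contrasts.

The caudoputamen divides into four cortical-input-defined territories —
dorsomedial (DMCP), lateral (LCP), tail (TCP), and anterior ventromedial
(aVMCP). Cells are assigned to parcels by label lookup, per-hemisphere
densities computed against parcel volumes, and composition tested with
random-intercept mixed models: subtype differences within each subregion and
subregion differences within each subtype, with all pairwise level contrasts
Sidak-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .mixedlm import (LmeFit, fit_fixed_only, fit_random_intercept,
                      wald_contrast, wald_omnibus)
from .points import SUBTYPES
from .volumes import LabelVolume

log = logging.getLogger(__name__)

SUBREGIONS = ("DMCP", "LCP", "TCP", "aVMCP")


@dataclass
class Parcellation:
    """Four-territory parcel volume with per-parcel volumes after region masking."""

    volume: LabelVolume
    volumes_mm3: dict[str, float]

    @property
    def names(self) -> list[str]:
        return [self.volume.label_map[l] for l in sorted(self.volume.label_map)]


def make_parcellation(parc_volume: LabelVolume, region: LabelVolume,
                      region_labels=(1,)) -> Parcellation:
    """Intersect a parcel label volume with the region mask and measure volumes."""
    if parc_volume.frame != region.frame:
        raise ValueError("parcellation and region are on different frames")
    if not parc_volume.label_map:
        raise ValueError("parcellation volume needs a label_map")
    region_mask = region.mask(region_labels)
    if parc_volume.labels.shape == region.labels.shape and \
            parc_volume.spacing_um == region.spacing_um:
        labels = np.where(region_mask, parc_volume.labels, 0)
        masked = LabelVolume(labels=labels, spacing_um=parc_volume.spacing_um,
                             frame=parc_volume.frame, label_map=dict(parc_volume.label_map))
    else:
        # different rasters: mask parcel voxels whose centres miss the region
        centers_all = parc_volume.voxel_centers_mm(parc_volume.labels > 0)
        inside = np.isin(region.labels_at_mm(centers_all), list(region_labels))
        labels = parc_volume.labels.copy()
        drop_idx = np.argwhere(parc_volume.labels > 0)[~inside]
        labels[drop_idx[:, 0], drop_idx[:, 1], drop_idx[:, 2]] = 0
        masked = LabelVolume(labels=labels, spacing_um=parc_volume.spacing_um,
                             frame=parc_volume.frame, label_map=dict(parc_volume.label_map))
    vvox = masked.spacing_mm ** 3
    volumes = {name: float((masked.labels == lab).sum() * vvox)
               for lab, name in masked.label_map.items()}
    return Parcellation(volume=masked, volumes_mm3=volumes)


def assign_subregion(cells: pd.DataFrame, parc: Parcellation) -> pd.DataFrame:
    """Add a ``subregion`` column by per-cell label lookup; "unassigned" off-parcel."""
    labels = parc.volume.labels_at_mm(cells[["ap_mm", "ml_mm", "dv_mm"]].to_numpy(dtype=float))
    name_of = dict(parc.volume.label_map)
    out = cells.copy()
    out["subregion"] = [name_of.get(int(l), "unassigned") for l in labels]
    n_un = int((out["subregion"] == "unassigned").sum())
    if n_un:
        log.info("subregion assignment: %d / %d cells unassigned", n_un, len(out))
    return out


def subregion_density_table(per_hemisphere_cells: dict[str, pd.DataFrame],
                            parc: Parcellation) -> pd.DataFrame:
    """Per-hemisphere densities (cells/mm³) for each subregion.

    One row per hemisphere × subregion; empty parcels give density 0;
    unassigned cells are excluded from densities.
    """
    bad = [n for n, v in parc.volumes_mm3.items() if v <= 0]
    if bad:
        raise ValueError(f"zero-volume parcels: {bad}")
    rows = []
    for hid in sorted(per_hemisphere_cells):
        cells = per_hemisphere_cells[hid]
        assigned = assign_subregion(cells, parc) if "subregion" not in cells.columns else cells
        subtype = cells["subtype"].iloc[0] if len(cells) else ""
        sex = cells["sex"].iloc[0] if len(cells) else ""
        counts = assigned[assigned["subregion"] != "unassigned"].groupby("subregion").size()
        for name, vol in parc.volumes_mm3.items():
            rows.append((hid, sex, subtype, name, float(counts.get(name, 0)) / vol))
    return pd.DataFrame(rows, columns=["hemisphere_id", "sex", "subtype", "subregion", "density"])


def sidak_adjust(p: float, m: int) -> float:
    """Family-wise Sidak correction: 1 - (1 - p)^m, clipped to [0, 1]."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return float(min(1.0, max(0.0, 1.0 - (1.0 - p) ** m)))


@dataclass
class CompositionResult:
    """Omnibus + pairwise contrasts for one stratum (a subregion or a subtype)."""

    stratum: str
    factor: str
    levels: list[str]
    fit: LmeFit
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float
    pairwise: pd.DataFrame
    interaction_p: float | None = None


def _factor_design(values: pd.Series, levels: list[str],
                   sex: pd.Series | None = None) -> pd.DataFrame:
    ref = levels[0]
    X = pd.DataFrame({"intercept": np.ones(len(values))})
    for lev in levels[1:]:
        X[lev] = (values == lev).astype(float).to_numpy()
    if sex is not None:
        male = (sex == "M").astype(float).to_numpy()
        X["sex_M"] = male
        for lev in levels[1:]:
            X[f"{lev}:sex_M"] = X[lev].to_numpy() * male
    return X


def _pairwise_contrasts(fit: LmeFit, levels: list[str]) -> pd.DataFrame:
    m = len(list(combinations(levels, 2)))
    rows = []
    for a, b in combinations(levels, 2):
        contrast = {}
        if a != levels[0]:
            contrast[a] = 1.0
        if b != levels[0]:
            contrast[b] = contrast.get(b, 0.0) - 1.0
        est, se, z, p = wald_contrast(fit, contrast)
        p_adj = sidak_adjust(p, m)
        rows.append((a, b, est, se, z, p, p_adj, p_adj < 0.05))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "estimate", "se", "z",
                                       "p_raw", "p_sidak", "significant"])


def composition_tests(table: pd.DataFrame, mode: str, with_sex: bool = False,
                      method: str = "ML", fixed_effects_only: bool = False) -> list[CompositionResult]:
    """Composition statistics over the subregion density table.

    ``mode="within_subregion"`` tests subtype differences inside each
    subregion (density ~ subtype + (1|hemisphere)); ``mode="within_subtype"``
    tests subregional differences inside each subtype. ``with_sex`` adds sex
    and factor×sex fixed effects and reports the interaction's omnibus p.
    ``fixed_effects_only`` drops the random intercept (the fallback for the
    within-subregion design where hemispheres are nested in subtypes).
    """
    if mode == "within_subregion":
        strata, factor, level_order = "subregion", "subtype", list(SUBTYPES)
    elif mode == "within_subtype":
        strata, factor, level_order = "subtype", "subregion", list(SUBREGIONS)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    results = []
    for stratum in sorted(table[strata].unique(), key=str):
        sub = table[table[strata] == stratum]
        levels = [l for l in level_order if l in set(sub[factor])]
        if len(levels) < 2:
            raise ValueError(f"stratum {stratum}: fewer than 2 levels of {factor}")
        if sub["hemisphere_id"].nunique() < 2:
            raise ValueError(f"stratum {stratum}: only one hemisphere")
        sex = sub["sex"] if with_sex else None
        X = _factor_design(sub[factor], levels, sex=sex)
        if fixed_effects_only:
            fit = fit_fixed_only(sub["density"].to_numpy(), X)
        else:
            fit = fit_random_intercept(sub["density"].to_numpy(), X,
                                       sub["hemisphere_id"].to_numpy(), method=method)
        chi2, df, p = wald_omnibus(fit, levels[1:])
        inter_p = None
        if with_sex:
            inter_names = [f"{lev}:sex_M" for lev in levels[1:]]
            _, _, inter_p = wald_omnibus(fit, inter_names)
        results.append(CompositionResult(
            stratum=str(stratum), factor=factor, levels=levels, fit=fit,
            omnibus_chi2=chi2, omnibus_df=df, omnibus_p=p,
            pairwise=_pairwise_contrasts(fit, levels), interaction_p=inter_p))
    return results
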