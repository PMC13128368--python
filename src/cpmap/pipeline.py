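"""End-to-end pipeline stages over a single YAML run configuration.

The configuration gathers the study's analysis constants in one audited
place — 150 μm voxels, 50/175 μm Chebyshev exclusions, 1,000 bootstrap
replicates, σ = 0.5 voxel smoothing, 15 quantile bins — together with input
paths, the coordinate frame, and the model options. Each stage reads the
same config, logs its in/out/dropped counts, and writes machine-readable
outputs plus a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, nrrd_io
from .density import (bootstrap_density, density_long_table, pooled_quantile_bins,
                      predominance, smooth)
from .frame import AXES, CoordinateFrame
from .gradients import (collapse_axis, fit_axis_gradient, fit_axis_sex_interaction,
                        fit_gradient_table, voxel_level_table)
from .grid import build_voxel_grid, chebyshev_exclude
from .points import (SUBTYPES, mirror_left_to_right, filter_to_region, read_cells,
                     sex_by_hemisphere, split_by_hemisphere, write_cells)
from .subregions import (composition_tests, make_parcellation, subregion_density_table)
from .synthetic import AtlasConfig, CellsConfig, SyntheticConfig, make_toy_atlas, simulate_cells
from .volumes import load_label_volume, save_label_volume

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Schema-checked pipeline configuration with the study defaults."""

    paths: dict = field(default_factory=dict)
    frame: CoordinateFrame = field(default_factory=CoordinateFrame)
    edge_um: float = 150.0
    d_boundary_um: float = 50.0
    d_ventricle_um: float = 175.0
    n_boot: int = 1000
    sigma_voxel: float = 0.5
    n_bins: int = 15
    bootstrap_unit: str = "hemisphere"
    lme_unit: str = "plane"
    method: str = "ML"
    sex: bool = True
    seed: int = 0
    schema: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            g = raw.get("grid", {})
            d = raw.get("density", {})
            m = raw.get("models", {})
            cfg = cls(
                paths=dict(raw.get("paths", {})),
                frame=CoordinateFrame.from_dict(raw.get("frame", {})),
                edge_um=float(g.get("edge_um", 150.0)),
                d_boundary_um=float(g.get("d_boundary_um", 50.0)),
                d_ventricle_um=float(g.get("d_ventricle_um", 175.0)),
                n_boot=int(d.get("n_boot", 1000)),
                sigma_voxel=float(d.get("sigma_voxel", 0.5)),
                n_bins=int(d.get("n_bins", 15)),
                bootstrap_unit=str(d.get("bootstrap_unit", "hemisphere")),
                lme_unit=str(m.get("lme_unit", "plane")),
                method=str(m.get("method", "ML")),
                sex=bool(m.get("sex", True)),
                seed=int(raw.get("seed", 0)),
                schema=dict(raw.get("schema", {})),
                synthetic=dict(raw.get("synthetic", {})),
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"bad configuration: {exc}") from exc
        if cfg.edge_um <= 0 or cfg.n_boot < 1 or cfg.n_bins < 2:
            raise ConfigError("edge_um must be > 0, n_boot >= 1, n_bins >= 2")
        if cfg.bootstrap_unit not in ("hemisphere", "cell"):
            raise ConfigError(f"bootstrap_unit must be hemisphere|cell, got {cfg.bootstrap_unit!r}")
        if cfg.lme_unit not in ("plane", "voxel"):
            raise ConfigError(f"lme_unit must be plane|voxel, got {cfg.lme_unit!r}")
        if cfg.method not in ("ML", "REML"):
            raise ConfigError(f"method must be ML|REML, got {cfg.method!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def out_dir(self) -> Path:
        out = Path(self.paths.get("out_dir", "cpmap_out"))
        out.mkdir(parents=True, exist_ok=True)
        return out


def _provenance(cfg: RunConfig, stage: str, extra: dict | None = None) -> dict:
    blob = json.dumps({**cfg.paths, "seed": cfg.seed, "edge_um": cfg.edge_um},
                      sort_keys=True).encode()
    return {
        "stage": stage,
        "cpmap_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        **(extra or {}),
    }


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _synthetic_from_dict(raw: dict, seed: int) -> SyntheticConfig:
    try:
        atlas = AtlasConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.get("atlas", {}).items()})
        cells_raw = {k: ({s: tuple(t) if isinstance(t, list) else t for s, t in v.items()}
                         if isinstance(v, dict) else v)
                     for k, v in raw.get("cells", {}).items()}
        cells = CellsConfig(**cells_raw)
    except TypeError as exc:
        raise ConfigError(f"bad synthetic block: {exc}") from exc
    return SyntheticConfig(atlas=atlas, cells=cells, seed=int(raw.get("seed", seed)))


def run_simulate(cfg: RunConfig, syn: SyntheticConfig | None = None) -> Path:
    """Write the toy atlas volumes (NRRD), synthetic cells (CSV) and truth JSON."""
    out = cfg.out_dir()
    syn = syn or _synthetic_from_dict(cfg.synthetic, cfg.seed)
    region, ventricle, parc, frame = make_toy_atlas(syn)
    cells = simulate_cells(syn, region, frame)

    save_label_volume(out / "region.nrrd", region)
    save_label_volume(out / "ventricle.nrrd", ventricle)
    save_label_volume(out / "parcellation.nrrd", parc.volume)
    _write_json(out / "parcellation_labels.json",
                {str(k): v for k, v in parc.volume.label_map.items()})
    write_cells(cells, out / "cells.csv")
    _write_json(out / "truth.json", {
        "frame": frame.to_dict(),
        "atlas": asdict(syn.atlas),
        "cells": {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in asdict(syn.cells).items()},
        "seed": syn.seed,
        "n_cells": int(len(cells)),
        "parcel_volumes_mm3": parc.volumes_mm3,
    })
    log.info("simulate: wrote %d cells and toy atlas to %s", len(cells), out)
    return out


def _load_inputs(cfg: RunConfig):
    frame = cfg.frame
    region = load_label_volume(cfg.paths["region"], frame, label_map={1: "CP"})
    ventricle = None
    if cfg.paths.get("ventricle"):
        ventricle = load_label_volume(cfg.paths["ventricle"], frame, label_map={1: "VL"})
    cells = read_cells(cfg.paths["cells_csv"], schema=cfg.schema)
    return frame, region, ventricle, cells


def _prepare(cfg: RunConfig):
    """Shared front end: mirror, filter, grid, exclusions."""
    frame, region, ventricle, cells = _load_inputs(cfg)
    n0 = len(cells)
    cells = mirror_left_to_right(cells, frame)
    cells = filter_to_region(cells, region, (1,))
    log.info("prepare: %d cells in, %d after region filter", n0, len(cells))
    grid = build_voxel_grid(region, (1,), edge_um=cfg.edge_um)
    grid = chebyshev_exclude(grid, region, ventricle,
                             d_boundary_um=cfg.d_boundary_um,
                             d_ventricle_um=cfg.d_ventricle_um)
    return frame, region, ventricle, cells, grid


def run_atlas(cfg: RunConfig) -> Path:
    """Density maps per subtype, pooled quantile bins, predominance map."""
    out = cfg.out_dir()
    frame, region, ventricle, cells, grid = _prepare(cfg)

    maps = {}
    for i, subtype in enumerate(s for s in SUBTYPES if s in set(cells["subtype"])):
        sub = cells[cells["subtype"] == subtype]
        dmap = bootstrap_density(split_by_hemisphere(sub), grid, n_boot=cfg.n_boot,
                                 seed=cfg.seed + i, subtype=subtype,
                                 unit=cfg.bootstrap_unit)
        maps[subtype] = smooth(dmap, cfg.sigma_voxel)
    if not maps:
        raise ValueError("no cells of any known subtype")

    binning = pooled_quantile_bins(list(maps.values()), n_bins=cfg.n_bins)
    for subtype, m in maps.items():
        nrrd_io.write(out / f"density_{subtype}_mean.nrrd", np.nan_to_num(m.mean),
                      spacings=[cfg.edge_um] * 3, encoding="gzip")
        nrrd_io.write(out / f"density_{subtype}_se.nrrd", np.nan_to_num(m.se),
                      spacings=[cfg.edge_um] * 3, encoding="gzip")
        nrrd_io.write(out / f"density_{subtype}_bin.nrrd", binning.bin_index[subtype],
                      spacings=[cfg.edge_um] * 3, encoding="gzip")
    if len(maps) >= 2:
        pred = predominance(maps)
        nrrd_io.write(out / "predominance.nrrd", pred.labels,
                      spacings=[cfg.edge_um] * 3, encoding="gzip")
        _write_json(out / "predominance_labels.json",
                    {str(k): v for k, v in pred.code_map.items()})
    density_long_table(maps, binning).to_csv(out / "density_voxels.csv", index=False,
                                             float_format="%.6f")
    _write_json(out / "atlas_provenance.json", _provenance(cfg, "atlas", {
        "n_cells": int(len(cells)),
        "n_candidate_voxels": None,
        "n_included_voxels": grid.n_included,
        "included_volume_mm3": grid.n_included * grid.voxel_volume_mm3,
        "quantile_thresholds": [float(t) for t in binning.thresholds],
    }))
    log.info("atlas: %d included voxels, %d subtype maps -> %s", grid.n_included, len(maps), out)
    return out


def run_gradients(cfg: RunConfig) -> Path:
    """Axis profiles and gradient mixed-model fits for every axis × subtype."""
    out = cfg.out_dir()
    frame, region, ventricle, cells, grid = _prepare(cfg)

    profile_rows, fits = [], {}
    for subtype in (s for s in SUBTYPES if s in set(cells["subtype"])):
        sub = cells[cells["subtype"] == subtype]
        by_hemi = split_by_hemisphere(sub)
        sexes = sex_by_hemisphere(sub)
        for j, axis in enumerate(AXES):
            if cfg.lme_unit == "voxel":
                table = voxel_level_table(by_hemi, grid, axis, sexes)
                fit = fit_gradient_table(table, method=cfg.method)
                slopes = None
            else:
                profile = collapse_axis(by_hemi, grid, axis, sexes, n_boot=cfg.n_boot,
                                        seed=cfg.seed + 10 * j, region=region)
                t = profile.table.assign(subtype=subtype, axis=axis)
                profile_rows.append(t)
                fit = fit_axis_gradient(profile, method=cfg.method)
                slopes = None
                if cfg.sex and profile.table["sex"].nunique() == 2:
                    _, slopes = fit_axis_sex_interaction(profile, method=cfg.method)
            entry = {"fit": fit.to_dict()}
            if slopes is not None:
                entry["sex_slopes"] = slopes
            fits[f"{subtype}_{axis}"] = entry
    if profile_rows:
        pd.concat(profile_rows, ignore_index=True)[
            ["hemisphere_id", "sex", "subtype", "axis", "plane_center_mm", "density"]
        ].to_csv(out / "axis_profiles.csv", index=False, float_format="%.6f")
    _write_json(out / "gradient_fits.json",
                {**fits, "provenance": _provenance(cfg, "gradients")})
    log.info("gradients: %d fits -> %s", len(fits), out)
    return out


def run_subregions(cfg: RunConfig) -> Path:
    """Subregion density table and composition statistics with Sidak contrasts."""
    out = cfg.out_dir()
    frame, region, ventricle, cells, grid = _prepare(cfg)
    if not cfg.paths.get("parcellation"):
        raise ConfigError("subregions stage needs paths.parcellation")
    label_path = cfg.paths.get("parcellation_labels")
    if label_path:
        with open(label_path) as fh:
            label_map = {int(k): v for k, v in json.load(fh).items()}
    else:
        label_map = {1: "DMCP", 2: "LCP", 3: "TCP", 4: "aVMCP"}
    parc_volume = load_label_volume(cfg.paths["parcellation"], cfg.frame, label_map=label_map)
    parc = make_parcellation(parc_volume, region, (1,))

    tables = []
    for subtype in (s for s in SUBTYPES if s in set(cells["subtype"])):
        sub = cells[cells["subtype"] == subtype]
        tables.append(subregion_density_table(split_by_hemisphere(sub), parc))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "subregion_densities.csv", index=False, float_format="%.6f")

    omnibus_rows, pair_rows = [], []
    for mode in ("within_subregion", "within_subtype"):
        with_sex = cfg.sex and table["sex"].nunique() == 2
        for res in composition_tests(table, mode, with_sex=with_sex, method=cfg.method):
            omnibus_rows.append({
                "mode": mode, "stratum": res.stratum, "factor": res.factor,
                "chi2": res.omnibus_chi2, "df": res.omnibus_df, "p": res.omnibus_p,
                "interaction_p": res.interaction_p,
                "sigma_u2": res.fit.sigma_u2, "sigma_e2": res.fit.sigma_e2,
                "n_obs": res.fit.n_obs, "n_groups": res.fit.n_groups,
            })
            pw = res.pairwise.assign(mode=mode, stratum=res.stratum)
            pair_rows.append(pw)
    pd.DataFrame(omnibus_rows).to_csv(out / "composition_omnibus.csv", index=False,
                                      float_format="%.6g")
    pd.concat(pair_rows, ignore_index=True).to_csv(out / "composition_pairwise.csv",
                                                   index=False, float_format="%.6g")
    _write_json(out / "subregion_provenance.json", _provenance(cfg, "subregions", {
        "parcel_volumes_mm3": parc.volumes_mm3,
    }))
    log.info("subregions: %d omnibus tests -> %s", len(omnibus_rows), out)
    return out


def run_report(cfg: RunConfig) -> Path:
    """Collect stage outputs in one summary JSON."""
    out = cfg.out_dir()
    summary: dict = {"provenance": _provenance(cfg, "report")}
    for name in ("truth.json", "atlas_provenance.json", "gradient_fits.json",
                 "subregion_provenance.json"):
        path = out / name
        if path.exists():
            with open(path) as fh:
                summary[name.removesuffix(".json")] = json.load(fh)
    _write_json(out / "report.json", summary)
    return out
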