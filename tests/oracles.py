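"""Independent brute-force implementations used as oracles in tests.

These deliberately use naive loops over raster/grid voxels and cells so they
share no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_candidate_inclusion(region, region_labels, edge_um):
    """Triple loop: a grid voxel is included iff it contains >=1 labeled raster
    voxel centre. Returns (origin_mm, shape, included)."""
    mask = np.isin(region.labels, list(region_labels))
    centers = region.voxel_centers_mm(mask)
    half = region.spacing_mm / 2.0
    origin = centers.min(axis=0) - half
    upper = centers.max(axis=0) + half
    edge = edge_um / 1000.0
    shape = tuple(int(np.ceil((upper[a] - origin[a]) / edge - 1e-9)) for a in range(3))
    included = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                lo = origin + np.array([i, j, k]) * edge
                hi = lo + edge
                inside = np.all((centers >= lo - 1e-12) & (centers < hi - 1e-12), axis=1)
                included[i, j, k] = bool(inside.any())
    return origin, shape, included


def linf_min_distance(point_mm, targets_mm):
    """Smallest Chebyshev distance (mm) from a point to any target centre."""
    if len(targets_mm) == 0:
        return np.inf
    return float(np.min(np.max(np.abs(targets_mm - point_mm), axis=1)))


def brute_chebyshev_excluded(grid, region, ventricle, region_labels,
                             d_boundary_um, d_ventricle_um):
    """Per included voxel: scan ALL exterior / ventricle raster voxel centres."""
    exterior = ~np.isin(region.labels, list(region_labels))
    ext_centers = region.voxel_centers_mm(exterior)
    vent_centers = (ventricle.voxel_centers_mm(ventricle.labels > 0)
                    if ventricle is not None else np.empty((0, 3)))
    excluded = []
    for center in grid.centers_mm:
        d_b = linf_min_distance(center, ext_centers) * 1000.0
        d_v = linf_min_distance(center, vent_centers) * 1000.0
        excluded.append(d_b < d_boundary_um - 1e-9 or d_v < d_ventricle_um - 1e-9)
    return np.array(excluded)


def brute_voxel_counts(cells, grid):
    """Per-cell floor-division binning into the grid; loops over rows."""
    counts = np.zeros(grid.shape, dtype=int)
    n_excluded = 0
    for _, row in cells.iterrows():
        pos = np.array([row.ap_mm, row.ml_mm, row.dv_mm])
        idx = np.floor((pos - grid.origin_mm) / grid.edge_mm + 1e-9).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)) or \
                not grid.included[idx[0], idx[1], idx[2]]:
            n_excluded += 1
        else:
            counts[idx[0], idx[1], idx[2]] += 1
    return counts, n_excluded


def brute_masked_gaussian(values, included, sigma):
    """Direct triple sum of the mask-renormalized truncated Gaussian."""
    radius = int(np.ceil(3.0 * sigma))
    out = np.full(values.shape, np.nan)
    shape = values.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not included[i, j, k]:
                    continue
                num = den = 0.0
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        for dk in range(-radius, radius + 1):
                            ii, jj, kk = i + di, j + dj, k + dk
                            if not (0 <= ii < shape[0] and 0 <= jj < shape[1]
                                    and 0 <= kk < shape[2]):
                                continue
                            if not included[ii, jj, kk]:
                                continue
                            w = np.exp(-(di * di + dj * dj + dk * dk) / (2.0 * sigma ** 2))
                            num += w * values[ii, jj, kk]
                            den += w
                out[i, j, k] = num / den
    return out


def brute_subregion_lookup(cells, parc):
    """Per-point parcel name by direct index arithmetic on the parcel raster."""
    vol = parc.volume
    names = []
    for _, row in cells.iterrows():
        pos = np.array([row.ap_mm, row.ml_mm, row.dv_mm])
        rel = (pos - np.asarray(vol.frame.origin_mm)) * np.asarray(vol.frame.axis_signs)
        idx = np.floor(rel / vol.spacing_mm + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(vol.labels.shape)):
            names.append("unassigned")
            continue
        lab = int(vol.labels[idx[0], idx[1], idx[2]])
        names.append(vol.label_map.get(lab, "unassigned"))
    return np.array(names)


def mixed_loglik_grid(y, X, groups, beta_grid, su2_grid, se2_grid):
    """Exhaustive Gaussian log-likelihood scan of the random-intercept model.

    Returns the best (loglik, beta, su2, se2) over the Cartesian grid; the
    marginal covariance per group is se2*I + su2*J evaluated directly.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    best = (-np.inf, None, None, None)
    uniq = np.unique(groups)
    for beta in beta_grid:
        resid = y - X @ np.asarray(beta)
        for su2 in su2_grid:
            for se2 in se2_grid:
                ll = 0.0
                for g in uniq:
                    r = resid[groups == g]
                    n = len(r)
                    V = se2 * np.eye(n) + su2 * np.ones((n, n))
                    sign, logdet = np.linalg.slogdet(V)
                    if sign <= 0:
                        ll = -np.inf
                        break
                    ll += -0.5 * (n * np.log(2 * np.pi) + logdet
                                  + r @ np.linalg.solve(V, r))
                if ll > best[0]:
                    best = (ll, np.asarray(beta), su2, se2)
    return best
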