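"""Random-intercept linear mixed models with Wald inference.

One shared engine backs both the axis-gradient fits and the subregion
composition tests: a Gaussian linear model with a single grouping factor
(hemisphere) contributing an additive random intercept,

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2).

Estimation is maximum likelihood by default (REML available) via
statsmodels' MixedLM; fixed effects are tested with Wald z statistics
(normal reference), appropriate at the observation counts these analyses
produce (hundreds of plane-level observations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

log = logging.getLogger(__name__)


@dataclass
class LmeFit:
    """A fitted random-intercept model: estimates, Wald inference, variances."""

    params: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    sigma_u2: float
    sigma_e2: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str
    cov: pd.DataFrame = field(repr=False)

    @property
    def names(self) -> list[str]:
        return list(self.params)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "method": self.method,
        }


def fit_random_intercept(response, fixed_design: pd.DataFrame, group,
                         method: str = "ML") -> LmeFit:
    """Fit y ~ X beta + (1 | group) by (restricted) maximum likelihood.

    ``fixed_design`` must carry named columns (include an intercept column
    explicitly). Rank-deficient designs raise naming the collinear columns.
    If the mixed optimization fails, the ordinary least-squares limit
    (sigma_u^2 = 0) is returned flagged ``converged=False``.
    """
    y = np.asarray(response, dtype=float)
    X = fixed_design.astype(float)
    group = np.asarray(group)
    if not (len(y) == len(X) == len(group)):
        raise ValueError("response, design and group lengths differ")
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be ML or REML, got {method!r}")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns that do not increase rank when added in order
        bad, r_prev, cols = [], 0, []
        for c in X.columns:
            cols.append(c)
            r = np.linalg.matrix_rank(X[cols].to_numpy())
            if r == r_prev:
                bad.append(c)
            r_prev = r
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")

    n_groups = len(np.unique(group))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = sm.MixedLM(y, X, groups=group)
            res = model.fit(reml=(method == "REML"))
            float(res.llf)  # force lazy evaluation inside the warning filter
        fe = res.fe_params
        cov = pd.DataFrame(np.asarray(res.cov_params())[: len(fe), : len(fe)],
                           index=list(X.columns), columns=list(X.columns))
        params = {c: float(fe[c]) for c in X.columns}
        se = {c: float(np.sqrt(cov.loc[c, c])) for c in X.columns}
        sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
        sigma_e2 = float(res.scale)
        loglik = float(res.llf)
        converged = bool(getattr(res, "converged", True))
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.warning("mixed fit failed (%s); falling back to OLS limit", exc)
        ols = sm.OLS(y, X).fit()
        params = {c: float(ols.params[c]) for c in X.columns}
        cov = pd.DataFrame(np.asarray(ols.cov_params()), index=list(X.columns),
                           columns=list(X.columns))
        se = {c: float(ols.bse[c]) for c in X.columns}
        sigma_u2, sigma_e2 = 0.0, float(ols.scale)
        loglik, converged = float(ols.llf), False

    zvals = {c: params[c] / se[c] if se[c] > 0 else np.nan for c in params}
    pvals = {c: float(2.0 * stats.norm.sf(abs(zvals[c]))) for c in params}
    return LmeFit(params=params, se=se, z=zvals, p=pvals, sigma_u2=sigma_u2,
                  sigma_e2=sigma_e2, loglik=loglik, n_obs=len(y),
                  n_groups=n_groups, converged=converged, method=method, cov=cov)


def fit_fixed_only(response, fixed_design: pd.DataFrame) -> LmeFit:
    """Ordinary least-squares fit presented as an LmeFit with sigma_u^2 = 0."""
    y = np.asarray(response, dtype=float)
    X = fixed_design.astype(float)
    ols = sm.OLS(y, X).fit()
    params = {c: float(ols.params[c]) for c in X.columns}
    se = {c: float(ols.bse[c]) for c in X.columns}
    cov = pd.DataFrame(np.asarray(ols.cov_params()), index=list(X.columns),
                       columns=list(X.columns))
    zvals = {c: params[c] / se[c] if se[c] > 0 else np.nan for c in params}
    pvals = {c: float(2.0 * stats.norm.sf(abs(zvals[c]))) for c in params}
    return LmeFit(params=params, se=se, z=zvals, p=pvals, sigma_u2=0.0,
                  sigma_e2=float(ols.scale), loglik=float(ols.llf), n_obs=len(y),
                  n_groups=len(y), converged=True, method="OLS", cov=cov)


def _negligible(fit: LmeFit) -> float:
    """Absolute scale below which estimates are numerical zero for this fit."""
    return 1e-9 * max(1.0, max(abs(v) for v in fit.params.values()))


def wald_contrast(fit: LmeFit, contrast: dict[str, float]) -> tuple[float, float, float, float]:
    """Wald test of w' beta = 0: returns (estimate, se, z, p)."""
    unknown = [c for c in contrast if c not in fit.params]
    if unknown:
        raise KeyError(f"unknown coefficients {unknown}; have {fit.names}")
    w = np.array([contrast.get(c, 0.0) for c in fit.names])
    beta = np.array([fit.params[c] for c in fit.names])
    est = float(w @ beta)
    var = float(w @ fit.cov.to_numpy() @ w)
    if abs(est) < _negligible(fit) and var < _negligible(fit) ** 2:
        return est, float(np.sqrt(max(var, 0.0))), 0.0, 1.0
    if var <= 0:
        return est, 0.0, np.nan, 1.0
    se = float(np.sqrt(var))
    z = est / se
    return est, se, float(z), float(2.0 * stats.norm.sf(abs(z)))


def wald_omnibus(fit: LmeFit, names: list[str]) -> tuple[float, int, float]:
    """Joint Wald chi-square test that all named coefficients are zero."""
    unknown = [c for c in names if c not in fit.params]
    if unknown:
        raise KeyError(f"unknown coefficients {unknown}")
    beta = np.array([fit.params[c] for c in names])
    sub = fit.cov.loc[names, names].to_numpy()
    df = len(names)
    # degenerate fits (zero residual variance) leave float noise in both the
    # estimates and their covariance; report a clean null instead of 0/0
    if np.all(np.abs(beta) < _negligible(fit)):
        return 0.0, df, 1.0
    chi2 = float(beta @ np.linalg.pinv(sub) @ beta)
    return chi2, df, float(stats.chi2.sf(chi2, df))
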