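"""Cross-sectional regressions over regions.

Pooled (period-aggregated) metrics per region are regressed on period-mean
covariates three ways: ordinary least squares, backward stepwise elimination
of non-significant covariates, and a maximum-likelihood spatial-lag model

    Y = rho * U Y + X beta + eps,    eps ~ N(0, sigma^2 I)

where U is a binary adjacency matrix between regions (1 for geographically
adjacent regions or regions connected by a bridge/tunnel).  U is used raw,
not row-standardized, so the admissible interval for the spatial
autoregressive parameter rho is (1/omega_min, 1/omega_max) with omega_min,
omega_max the extreme real eigenvalues of U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "AdjacencyMatrix",
    "CrossFit",
    "build_adjacency",
    "period_means",
    "fit_ols",
    "fit_spatial_lag",
    "backward_eliminate",
]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric binary adjacency over an explicit region ordering."""

    matrix: np.ndarray
    regions: tuple

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if m.shape[0] != len(self.regions):
            raise ValueError("region list does not match matrix size")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if m.sum() == 0:
            raise ValueError("adjacency has no edges")
        object.__setattr__(self, "matrix", m.astype(float))

    @property
    def n(self) -> int:
        return len(self.regions)


def build_adjacency(edges, regions) -> AdjacencyMatrix:
    """Build a symmetric 0/1 adjacency from an undirected edge list.

    Rejects self-edges, endpoints outside ``regions``, and an empty edge
    list (a null graph makes the spatial term vacuous).
    """
    regions = tuple(regions)
    index = {r: i for i, r in enumerate(regions)}
    if not edges:
        raise ValueError("empty edge list: adjacency would be the null graph")
    m = np.zeros((len(regions), len(regions)))
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-edge on region {a!r}")
        if a not in index or b not in index:
            unknown = [r for r in (a, b) if r not in index]
            raise ValueError(f"edge references unknown region(s): {unknown}")
        m[index[a], index[b]] = 1.0
        m[index[b], index[a]] = 1.0
    return AdjacencyMatrix(m, regions)


def period_means(covariates: pd.DataFrame, years: tuple[int, int] | None = None,
                 min_coverage: float = 0.5) -> pd.DataFrame:
    """Average covariates over a period, per region.

    ``covariates`` is long-format with columns region, year, variable, value.
    Missing years are ignored, but each (region, variable) must cover at
    least ``min_coverage`` of the period's years.
    """
    df = covariates.dropna(subset=["value"])
    if years is not None:
        df = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
        span = years[1] - years[0] + 1
    else:
        span = df["year"].nunique()
    counts = df.groupby(["region", "variable"])["value"].count()
    thin = counts[counts < min_coverage * span]
    if len(thin):
        raise ValueError(
            f"insufficient coverage (<{min_coverage:.0%} of {span} years) for: "
            f"{list(thin.index[:5])}")
    wide = df.groupby(["region", "variable"])["value"].mean().unstack("variable")
    return wide


@dataclass
class CrossFit:
    """A fitted cross-sectional regression.

    ``table`` has one row per term (including ``const``) with columns
    ``coef``, ``se``, ``p``.  ``rho`` is the spatial autoregressive
    parameter (None for OLS).  ``r2`` is the classical R^2 for OLS and a
    pseudo-R^2 (squared correlation of fitted vs observed) for the spatial
    model.
    """

    table: pd.DataFrame
    r2: float
    n: int
    rho: float | None = None
    rho_se: float | None = None
    rho_p: float | None = None
    loglik: float | None = None
    intercept_only: bool = False
    elimination_trace: list = field(default_factory=list)

    @property
    def pvalues(self) -> pd.Series:
        """p-values of the non-intercept terms."""
        return self.table.loc[self.table.index != "const", "p"]

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])


def _design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.atleast_2d(np.asarray(X, dtype=float))
        if mat.shape[0] == 1 and mat.shape[1] > 1:
            mat = mat.T
        names = [f"x{i}" for i in range(mat.shape[1])]
    if np.isnan(mat).any():
        raise ValueError("design matrix contains missing values")
    return mat, names


def _check_rank(mat: np.ndarray, names: list[str]) -> None:
    full = np.column_stack([np.ones(len(mat)), mat])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        # identify columns involved in the collinearity by leave-one-out rank
        guilty = [nm for j, nm in enumerate(names)
                  if np.linalg.matrix_rank(np.delete(full, j + 1, axis=1))
                  == np.linalg.matrix_rank(full)]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {guilty}")


def fit_ols(y, X) -> CrossFit:
    """Ordinary least squares with classical (t-based) inference."""
    yv = np.asarray(y, dtype=float)
    mat, names = _design(X)
    if np.isnan(yv).any():
        raise ValueError("response contains missing values")
    if len(yv) <= mat.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    _check_rank(mat, names)
    res = sm.OLS(yv, sm.add_constant(pd.DataFrame(mat, columns=names))).fit()
    table = pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
    return CrossFit(table=table, r2=float(res.rsquared), n=int(res.nobs),
                    loglik=float(res.llf))


# ---------------------------------------------------------------------------
# Maximum-likelihood spatial lag model
# ---------------------------------------------------------------------------

def _sar_loglik(rho: float, beta: np.ndarray, y: np.ndarray, Xc: np.ndarray,
                U: np.ndarray, omega: np.ndarray) -> float:
    """Full log-likelihood with sigma^2 profiled out."""
    n = len(y)
    e = y - rho * (U @ y) - Xc @ beta
    sigma2 = float(e @ e) / n
    logdet = float(np.sum(np.log(1.0 - rho * omega)))
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet


def fit_spatial_lag(y, X, U: AdjacencyMatrix | np.ndarray | None,
                    rho_fixed: float | None = None) -> CrossFit:
    """Maximum-likelihood fit of Y = rho*UY + X beta + eps.

    The likelihood is concentrated: for each rho, beta is the OLS fit of
    (I - rho U)Y on [1 X] and sigma^2 the mean squared residual; the
    concentrated log-likelihood adds the Jacobian term log|I - rho U| =
    sum_i log(1 - rho omega_i).  rho is restricted to the interval where
    all 1 - rho*omega_i > 0.  Standard errors come from the observed
    information (numerical Hessian of the profile log-likelihood in
    (rho, beta)); p-values are asymptotic-normal.

    ``U=None`` drops the spatial term and delegates to :func:`fit_ols`.
    ``rho_fixed`` skips the rho search (mainly for cross-checks).
    """
    if U is None:
        return fit_ols(y, X)
    Um = U.matrix if isinstance(U, AdjacencyMatrix) else np.asarray(U, dtype=float)
    yv = np.asarray(y, dtype=float)
    mat, names = _design(X)
    _check_rank(mat, names)
    n = len(yv)
    if Um.shape != (n, n):
        raise ValueError("adjacency size does not match sample size")
    Xc = np.column_stack([np.ones(n), mat])
    omega = np.linalg.eigvalsh(Um)
    w_min, w_max = omega[0], omega[-1]
    if w_max <= 0 or w_min >= 0:
        raise ValueError("adjacency eigenvalues do not bracket zero")
    lo, hi = 1.0 / w_min, 1.0 / w_max

    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    proj = XtX_inv @ Xc.T

    def beta_at(rho: float) -> np.ndarray:
        return proj @ (yv - rho * (Um @ yv))

    def neg_conc(rho: float) -> float:
        return -_sar_loglik(rho, beta_at(rho), yv, Xc, Um, omega)

    if rho_fixed is not None:
        rho_hat = float(rho_fixed)
    else:
        eps = 1e-6 * (hi - lo)
        res = optimize.minimize_scalar(neg_conc, bounds=(lo + eps, hi - eps),
                                       method="bounded", options={"xatol": 1e-9})
        rho_hat = float(res.x)
        if min(rho_hat - lo, hi - rho_hat) < 1e-4 * (hi - lo):
            warnings.warn(f"rho estimate {rho_hat:.4f} is at the admissible "
                          f"interval boundary ({lo:.4f}, {hi:.4f})",
                          RuntimeWarning, stacklevel=2)
    beta_hat = beta_at(rho_hat)
    ll = _sar_loglik(rho_hat, beta_hat, yv, Xc, Um, omega)

    # observed information of the profile log-likelihood in (rho, beta)
    params = np.concatenate([[rho_hat], beta_hat])

    def ll_vec(p: np.ndarray) -> float:
        return _sar_loglik(p[0], p[1:], yv, Xc, Um, omega)

    H = _num_hessian(ll_vec, params)
    try:
        cov = np.linalg.inv(-H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(len(params), np.nan)
    rho_se = float(se_all[0])
    se = se_all[1:]
    z = np.divide(beta_hat, se, out=np.full_like(beta_hat, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"coef": beta_hat, "se": se, "p": p},
                         index=["const"] + names)
    fitted = rho_hat * (Um @ yv) + Xc @ beta_hat
    if np.std(fitted) > 0 and np.std(yv) > 0:
        pseudo_r2 = float(np.corrcoef(fitted, yv)[0, 1] ** 2)
    else:
        pseudo_r2 = 0.0
    rho_z = rho_hat / rho_se if rho_se > 0 else np.nan
    return CrossFit(table=table, r2=pseudo_r2, n=n, rho=rho_hat, rho_se=rho_se,
                    rho_p=float(2 * stats.norm.sf(abs(rho_z))), loglik=ll)


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Backward stepwise elimination
# ---------------------------------------------------------------------------

def backward_eliminate(y, X: pd.DataFrame, alpha: float = 0.05,
                       fitter=fit_ols, **fitter_kwargs) -> CrossFit:
    """Drop the least significant covariate until all retained have p < alpha.

    One variable is removed per step — the one with the largest p-value at
    or above ``alpha`` — and the model is refitted, the conventional
    backward-elimination reading of "stepwise".  If everything is
    eliminated, an intercept-only fit is returned with ``intercept_only``
    set.  The removal sequence is recorded in ``elimination_trace``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)))
    cols = list(X.columns)
    trace: list[tuple[str, float]] = []
    while cols:
        fit = fitter(y, X[cols], **fitter_kwargs)
        pv = fit.pvalues
        worst = pv.idxmax()
        if pv.loc[worst] < alpha:
            fit.elimination_trace = trace
            return fit
        trace.append((worst, float(pv.loc[worst])))
        cols.remove(worst)
    # intercept-only: mean model
    yv = np.asarray(y, dtype=float)
    res = sm.OLS(yv, np.ones((len(yv), 1))).fit()
    table = pd.DataFrame({"coef": [res.params[0]], "se": [res.bse[0]],
                          "p": [res.pvalues[0]]}, index=["const"])
    return CrossFit(table=table, r2=0.0, n=len(yv), intercept_only=True,
                    elimination_trace=trace)
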