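"""Lagged/smoothed panel regression with serial correlation.

Covariates are replaced by trailing window means: the value regressed
against the dependent variable at year j is the mean of the covariate over
calendar years [j-G-W, j-G+W] inclusive, where G is the lag and W the
smoothing radius.  (G, W) is chosen per covariate by grid search to maximize
the overall R^2 of a random-effect AR(1) panel regression

    Y_ij = alpha + X_ij beta + nu_i + eps_ij,
    eps_ij = phi * eps_{i,j-1} + eta_ij

with region random effects nu_i and a single serial-correlation coefficient
phi shared across regions.  Estimation is two-step feasible GLS:

1. pooled OLS for a consistent first pass;
2. phi from the lag-1 autocorrelation of within-region-demeaned residuals,
   with the first-order Nickell correction phi + (1 + 3*phi)/T-bar for the
   downward bias that demeaning induces in short panels;
3. Prais-Winsten quasi-differencing within each region's consecutive runs;
4. closed-form random-effects (Swamy-Arora) GLS on the transformed data.

The "overall R^2" used for lag selection is the squared correlation between
the fixed-part fitted values (alpha + X beta) and the observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LagSpec",
    "PanelFit",
    "lag_smooth",
    "window_years",
    "interpolate_biennial",
    "fit_re_ar1",
    "overall_r2",
    "grid_search_lag",
]


@dataclass(frozen=True)
class LagSpec:
    """Lag G and smoothing radius W, both in whole years."""

    G: int
    W: int

    def __post_init__(self) -> None:
        if self.G < 0 or self.W < 0:
            raise ValueError("G and W must be non-negative")
        if self.G != int(self.G) or self.W != int(self.W):
            raise ValueError("G and W must be whole years")


def window_years(year: int, G: int, W: int) -> range:
    """Calendar years averaged for a dependent-variable year: [j-G-W, j-G+W]."""
    return range(year - G - W, year - G + W + 1)


def lag_smooth(series: pd.Series, G: int, W: int) -> pd.Series:
    """Window-mean transform of a (region, year)-indexed covariate series.

    The value at (i, j) is the mean of the series over the 2W+1 calendar
    years [j-G-W, j-G+W]; if any year of the window is unavailable for that
    region the result is missing (no partial windows — a shrinking window
    would silently change the lag structure near the record start).
    """
    spec = LagSpec(G, W)
    wide = series.unstack("year") if isinstance(series.index, pd.MultiIndex) \
        else series.to_frame().T
    years = wide.columns.to_numpy()
    full = np.arange(years.min(), years.max() + 1)
    wide = wide.reindex(columns=full)
    vals = wide.to_numpy(dtype=float)
    out = _window_means(vals, spec.G, spec.W)
    result = pd.DataFrame(out, index=wide.index, columns=full).stack(
        future_stack=True)
    result.index.names = ["region", "year"]
    result.name = series.name
    return result


def _window_means(vals: np.ndarray, G: int, W: int) -> np.ndarray:
    """Window means aligned to dependent years, columns = contiguous years.

    Column j gets the mean of columns [j-G-W, j-G+W]; NaN where the window
    leaves the record or contains a missing value (NaN propagates through
    the plain mean, which is exactly the no-partial-window rule).
    """
    n_years = vals.shape[1]
    width = 2 * W + 1
    out = np.full_like(vals, np.nan, dtype=float)
    if width > n_years:
        return out
    sw = np.lib.stride_tricks.sliding_window_view(vals, width, axis=1)
    means = sw.mean(axis=-1)  # window starting at column s spans [s, s+2W]
    # dependent year index j satisfies j - G - W == s
    dep = np.arange(means.shape[1]) + G + W
    ok = dep < n_years
    out[:, dep[ok]] = means[:, ok]
    return out


def interpolate_biennial(series: pd.Series) -> pd.Series:
    """Fill single-year gaps by the mean of the flanking observed values.

    Intended for biennially surveyed covariates.  Observed values are never
    touched, there is no extrapolation beyond the observed range, and gaps
    longer than one year are left missing with a warning.
    """
    def fill_region(s: pd.Series) -> pd.Series:
        s = s.sort_index()
        obs = s.dropna()
        if obs.empty:
            return s
        full = pd.Series(index=range(int(obs.index.min()), int(obs.index.max()) + 1),
                         dtype=float)
        full.loc[obs.index] = obs
        filled = full.copy()
        for y in full.index[full.isna()]:
            before, after = full.get(y - 1), full.get(y + 1)
            if before is not None and after is not None and \
                    np.isfinite(before) and np.isfinite(after):
                filled.loc[y] = 0.5 * (before + after)
        if filled.isna().any():
            warnings.warn(
                f"gaps longer than one year left missing at years "
                f"{list(filled.index[filled.isna()])[:5]}",
                RuntimeWarning, stacklevel=3)
        return filled

    if isinstance(series.index, pd.MultiIndex):
        parts = {r: fill_region(series.xs(r, level="region"))
                 for r in series.index.get_level_values("region").unique()}
        out = pd.concat(parts, names=["region", "year"])
    else:
        out = fill_region(series)
    out.name = series.name
    return out


@dataclass
class PanelFit:
    """A fitted random-effect AR(1) panel regression.

    ``table`` has one row per term (including ``const``) with ``coef``,
    ``se``, ``p``.  ``phi`` is the serial-correlation coefficient,
    ``sigma2_nu`` / ``sigma2_eta`` the random-effect and innovation
    variances, ``overall_r2`` the squared correlation of the fixed-part
    prediction with the observations, ``n`` the complete cases used, and
    ``specs`` the LagSpec applied to each covariate (empty when the caller
    lagged the covariates itself).
    """

    table: pd.DataFrame
    phi: float
    sigma2_nu: float
    sigma2_eta: float
    overall_r2: float
    n: int
    specs: dict[str, LagSpec] = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.table.loc["const", "coef"])

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])

    @property
    def pvalues(self) -> pd.Series:
        return self.table.loc[self.table.index != "const", "p"]


def _complete_panel(y: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    df = pd.concat([y.rename("_y"), X], axis=1, join="inner").dropna()
    if df.empty:
        raise ValueError("no complete cases after aligning y with X")
    return df.sort_index()


def fit_re_ar1(y: pd.Series, X: pd.DataFrame, min_run: int = 3) -> PanelFit:
    """Two-step FGLS for the random-effect AR(1) panel model.

    ``y`` and ``X`` are (region, year)-indexed; rows with any missing value
    are dropped (complete-case).  Regions contributing fewer than
    ``min_run`` consecutive years are dropped with a warning, since phi is
    identified from within-region consecutive pairs.  Raises if the
    estimated |phi| >= 1.
    """
    if isinstance(X, pd.Series):
        X = X.to_frame()
    df = _complete_panel(y, X)
    names = [str(c) for c in df.columns if c != "_y"]

    regions = df.index.get_level_values("region")
    groups0, labels = pd.factorize(regions)
    yrs_all = df.index.get_level_values("year").to_numpy()
    # a row continues a run when the previous row is the same region's
    # previous calendar year (df is sorted by region then year)
    prev_same = np.zeros(len(df), dtype=bool)
    prev_same[1:] = (groups0[1:] == groups0[:-1]) & (yrs_all[1:] == yrs_all[:-1] + 1)

    return _re_ar1_core(df["_y"].to_numpy(), df[names].to_numpy(),
                        groups0, prev_same, names, min_run,
                        region_labels=list(labels))


def _re_ar1_core(yv: np.ndarray, Xv: np.ndarray, groups0: np.ndarray,
                 prev_same: np.ndarray, names: list[str], min_run: int = 3,
                 region_labels: list | None = None) -> PanelFit:
    """Array core of :func:`fit_re_ar1`.

    ``groups0`` are integer region codes for rows sorted region-major with
    ascending years; ``prev_same`` flags rows whose predecessor is the same
    region's previous calendar year.
    """
    # drop regions whose longest consecutive run is too short to inform phi
    run_id = np.cumsum(~prev_same)
    run_len = np.bincount(run_id)[run_id]
    max_run = np.zeros(groups0.max() + 1, dtype=int)
    np.maximum.at(max_run, groups0, run_len)
    keep_mask = max_run[groups0] >= min_run
    if not keep_mask.all():
        bad = np.flatnonzero(max_run < min_run)
        shown = [region_labels[i] for i in bad[:5]] if region_labels else bad[:5].tolist()
        warnings.warn(f"dropping {len(bad)} region(s) with < {min_run} "
                      f"consecutive years: {shown}",
                      RuntimeWarning, stacklevel=3)
        if not keep_mask.any():
            raise ValueError("no regions with enough consecutive years")
        yv, Xv = yv[keep_mask], Xv[keep_mask]
        groups0 = groups0[keep_mask]
        prev_same = prev_same[keep_mask]
    groups = pd.factorize(groups0)[0]
    n_regions = groups.max() + 1

    n = len(yv)
    Xc = np.column_stack([np.ones(n), Xv])
    k = Xc.shape[1]
    if n <= k:
        raise ValueError("too few complete cases for the design")

    # step 1: pooled OLS (consistent under random effects)
    beta0, *_ = np.linalg.lstsq(Xc, yv, rcond=None)
    resid = yv - Xc @ beta0

    # step 2: phi from lag-1 autocorrelation of within-region-demeaned
    # residuals over consecutive year pairs
    T_i = np.bincount(groups)
    rmean = np.bincount(groups, resid) / T_i
    rd = resid - rmean[groups]
    pair = np.flatnonzero(prev_same)
    num = float(rd[pair] @ rd[pair - 1])
    den = float(rd[pair - 1] @ rd[pair - 1])
    phi_raw = num / den if den > 0 else 0.0
    if abs(phi_raw) >= 1:
        raise ValueError(f"estimated serial correlation |phi| >= 1 ({phi_raw:.3f})")
    # first-order small-T bias correction (within-demeaning biases the
    # lag-1 autocorrelation by about -(1 + 3*phi)/T)
    t_bar = n / n_regions
    phi = phi_raw + (1.0 + 3.0 * phi_raw) / t_bar
    if abs(phi) >= 1:
        warnings.warn(f"bias-corrected phi {phi:.3f} clipped to +/-0.99",
                      RuntimeWarning, stacklevel=3)
        phi = float(np.clip(phi, -0.99, 0.99))

    # step 3: Prais-Winsten quasi-differencing within consecutive runs
    # (run-initial rows are scaled by sqrt(1 - phi^2))
    c = np.sqrt(1.0 - phi ** 2)
    y_t = np.where(prev_same, yv - phi * np.roll(yv, 1), c * yv)
    X_t = np.where(prev_same[:, None], Xc - phi * np.roll(Xc, 1, axis=0), c * Xc)

    # step 4: Swamy-Arora random-effects GLS on the transformed data.
    # Within (region-demeaned) regression gives sigma2_eta; the between
    # regression of region means gives sigma2_nu.
    def demean(a):
        means = np.zeros((n_regions,) + a.shape[1:])
        np.add.at(means, groups, a)
        means /= T_i.reshape(-1, *([1] * (a.ndim - 1)))
        return a - means[groups], means

    Xw, Xbar = demean(X_t)
    yw, ybar = demean(y_t)
    # within fit; the quasi-differenced intercept column does not demean to
    # zero (run-initial rows are scaled differently), so it stays in
    bw, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rw = yw - Xw @ bw
    dof_w = max(n - n_regions - k, 1)
    sigma2_eta = float(rw @ rw) / dof_w
    # between fit on region means
    if n_regions > k:
        bb, *_ = np.linalg.lstsq(Xbar, ybar, rcond=None)
        rb = ybar - Xbar @ bb
        s2_between = float(T_i @ rb ** 2) / (n_regions - k)
        sigma2_nu = max(s2_between - sigma2_eta, 0.0) / (n / n_regions)
    else:
        sigma2_nu = 0.0

    # GLS by partial demeaning with region-specific theta
    theta_i = 1.0 - np.sqrt(sigma2_eta / (T_i * sigma2_nu + sigma2_eta))
    lam = theta_i[groups]
    Xg = X_t - lam[:, None] * Xbar[groups]
    yg = y_t - lam * ybar[groups]
    XtX = Xg.T @ Xg
    beta = np.linalg.solve(XtX, Xg.T @ yg)
    r = yg - Xg @ beta
    s2 = float(r @ r) / max(n - k, 1)
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    t = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * stats.t.sf(np.abs(t), df=max(n - k, 1))
    table = pd.DataFrame({"coef": beta, "se": se, "p": p},
                         index=["const"] + names)

    pred = Xc @ beta
    if np.std(pred) > 0 and np.std(yv) > 0:
        r2 = float(np.corrcoef(pred, yv)[0, 1] ** 2)
    else:
        r2 = 0.0
    return PanelFit(table=table, phi=float(phi), sigma2_nu=float(sigma2_nu),
                    sigma2_eta=float(sigma2_eta), overall_r2=r2, n=n)


def overall_r2(fit: PanelFit, y: pd.Series, X: pd.DataFrame) -> float:
    """Squared correlation of the fixed-part prediction with observations.

    Only alpha + X beta enters the prediction; random effects and the AR
    process are excluded, so this measures what the covariates alone
    explain.  Returns 0 when either vector is degenerate.
    """
    if isinstance(X, pd.Series):
        X = X.to_frame()
    df = _complete_panel(y, X)
    names = [c for c in df.columns if c != "_y"]
    pred = fit.intercept + df[names].to_numpy() @ fit.table.loc[names, "coef"].to_numpy()
    obs = df["_y"].to_numpy()
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def grid_search_lag(y: pd.Series, x: pd.Series,
                    G_range=range(0, 31), W_range=range(1, 6),
                    fit_years: tuple[int, int] = (2000, 2010),
                    min_run: int = 3) -> tuple[LagSpec, PanelFit, pd.DataFrame]:
    """Select the (G, W) maximizing overall R^2 for a single covariate.

    Fits the random-effect AR(1) model for every (G, W) in the grid,
    restricting the dependent variable to ``fit_years``.  W = 0 is excluded
    (point lags give unstable R^2-vs-G profiles).  Ties are broken by
    smallest G, then smallest W.  Returns the winning spec, its fit, and
    the full R^2 surface (columns G, W, r2, n) for plotting; grid cells
    with no usable complete cases are recorded with NaN.
    """
    G_range, W_range = list(G_range), list(W_range)
    if any(w < 1 for w in W_range):
        raise ValueError("lag selection requires W >= 1")

    years = y.index.get_level_values("year")
    y_fit = y[(years >= fit_years[0]) & (years <= fit_years[1])].dropna()
    x = x.dropna()
    regions = sorted(set(y_fit.index.get_level_values("region"))
                     & set(x.index.get_level_values("region")))
    if not regions:
        raise ValueError("y and x share no regions")
    dep_years = np.arange(fit_years[0], fit_years[1] + 1)
    y_wide = (y_fit.unstack("year")
              .reindex(index=regions, columns=dep_years).to_numpy(dtype=float))

    x_wide = x.unstack("year").reindex(index=regions)
    x_years = x_wide.columns.to_numpy()
    full = np.arange(x_years.min(), x_years.max() + 1)
    x_wide = x_wide.reindex(columns=full)
    xv = x_wide.to_numpy(dtype=float)

    n_r, n_t = y_wide.shape
    rows = []
    best: tuple[LagSpec, PanelFit] | None = None
    for W in W_range:
        width = 2 * W + 1
        if width > len(full):
            for G in G_range:
                rows.append({"G": G, "W": W, "r2": np.nan, "n": 0})
            continue
        sw = np.lib.stride_tricks.sliding_window_view(xv, width, axis=1)
        means = sw.mean(axis=-1)  # start column s covers years [s, s+2W]
        for G in G_range:
            # dependent year j uses the window starting at j - G - W
            starts = np.searchsorted(full, dep_years) - G - W
            ok = (starts >= 0) & (starts < means.shape[1]) & \
                 (dep_years >= full[0] + G + W)
            x_dep = np.full((n_r, n_t), np.nan)
            x_dep[:, ok] = means[:, starts[ok]]
            mask = np.isfinite(y_wide) & np.isfinite(x_dep)
            if mask.sum() <= 3:
                rows.append({"G": G, "W": W, "r2": np.nan, "n": 0})
                continue
            idx = np.flatnonzero(mask.ravel())
            prev = np.zeros_like(mask)
            prev[:, 1:] = mask[:, :-1] & mask[:, 1:]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = _re_ar1_core(
                        y_wide.ravel()[idx], x_dep.ravel()[idx][:, None],
                        idx // n_t, prev.ravel()[idx], ["x"], min_run,
                        region_labels=regions)
            except ValueError:
                rows.append({"G": G, "W": W, "r2": np.nan, "n": 0})
                continue
            rows.append({"G": G, "W": W, "r2": fit.overall_r2, "n": fit.n})
            if best is None or fit.overall_r2 > best[1].overall_r2 + 1e-12 or \
                    (abs(fit.overall_r2 - best[1].overall_r2) <= 1e-12
                     and (G, W) < (best[0].G, best[0].W)):
                best = (LagSpec(G, W), fit)
    surface = pd.DataFrame(rows).sort_values(["G", "W"]).reset_index(drop=True)
    if best is None:
        raise ValueError("no (G, W) cell produced a fit; covariate record too short")
    spec, fit = best
    fit.specs = {str(x.name or "x"): spec}
    return spec, fit, surface
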