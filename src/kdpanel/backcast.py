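"""Retrograde reconstruction of national metrics from a fertility series.

A univariate panel model fitted at region level (normalized metric on a
lag/smoothed total fertility rate) is applied to a *national* TFR series to
reconstruct — and extrapolate backwards in time — the national trajectory of
the metric on its original scale.  Only the fixed part alpha + beta * x is
used: random effects and the AR noise process are region-level and average
out nationally.  Transferring a region-level model to the national series is
a modelling leap; the provenance manifest records every ingredient (lag
spec, Box-Cox theta, coefficients, fit period) so the step is explicit and
the output exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .normalize import inverse_transform
from .panel_lag import LagSpec, PanelFit, window_years

__all__ = ["ReconstructionResult", "reconstruct"]


@dataclass
class ReconstructionResult:
    """Backcast predictions plus the provenance that determines them."""

    predictions: pd.Series  # year -> metric on the original scale
    provenance: dict = field(default_factory=dict)


def _validate_national(series: pd.Series) -> pd.Series:
    s = series.dropna().sort_index()
    if (s <= 0).any():
        raise ValueError("national series must be strictly positive")
    yrs = s.index.to_numpy()
    if len(yrs) > 1 and not (np.diff(yrs) == 1).all():
        raise ValueError("national series years must be contiguous")
    return s


def reconstruct(series: pd.Series, fit: PanelFit, theta: float, spec: LagSpec,
                target_years: Iterable[int],
                covariate: str | None = None) -> ReconstructionResult:
    """Predict a metric for ``target_years`` from a national covariate series.

    For each target year j the normalized prediction is
    alpha + beta * mean(series over [j-G-W, j-G+W]); the inverse Box-Cox
    with ``theta`` returns it to the original scale, clamped below at 0.
    Years whose window extends beyond the series are reported missing with
    a warning — retrograde extrapolation stops where the covariate record
    stops, it is never padded.
    """
    s = _validate_national(series)
    names = [ix for ix in fit.table.index if ix != "const"]
    if covariate is None:
        if len(names) != 1:
            raise ValueError("fit is multivariate; name the covariate to use")
        covariate = names[0]
    beta = fit.coef(covariate)
    alpha = fit.intercept

    years = sorted(int(j) for j in target_years)
    preds, missing = {}, []
    for j in years:
        w = list(window_years(j, spec.G, spec.W))
        if w[0] < s.index.min() or w[-1] > s.index.max():
            preds[j] = np.nan
            missing.append(j)
            continue
        xw = float(s.loc[w[0]:w[-1]].mean())
        normalized = alpha + beta * xw
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            value = float(inverse_transform(normalized, theta, floor=0.0))
        preds[j] = max(value, 0.0)
    if missing:
        warnings.warn(f"insufficient national-series coverage for {len(missing)} "
                      f"target year(s): {missing[:5]}", RuntimeWarning, stacklevel=2)
    out = pd.Series(preds, name="predicted").sort_index()
    out.index.name = "year"
    provenance = {
        "covariate": covariate,
        "lag_spec": {"G": spec.G, "W": spec.W},
        "theta": float(theta),
        "intercept": alpha,
        "coefficient": beta,
        "fit_n": fit.n,
        "series_span": [int(s.index.min()), int(s.index.max())],
        "target_years": years,
        "missing_years": missing,
    }
    return ReconstructionResult(predictions=out, provenance=provenance)
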