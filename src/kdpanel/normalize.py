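"""Box-Cox normalization of dependent variables, and its inverse.

Dependent variables (incidence, mean patient age) are skewed; each regression
normalizes them with a one-parameter power transform

    y' = (y**theta - 1) / theta   (theta != 0),   y' = ln y   (theta == 0)

with theta estimated by maximizing the Box-Cox profile log-likelihood.  The
inverse transform maps model predictions back to the original scale for
reconstruction; backcasts can leave the admissible range of the inverse, in
which case values are clamped to a configurable floor with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["BoxCoxModel", "transform", "inverse_transform", "fit_theta"]


@dataclass(frozen=True)
class BoxCoxModel:
    """A fitted power-transform parameter and where it came from."""

    theta: float
    loglik: float
    fitted_on: str = ""


def _check_positive(y: np.ndarray) -> None:
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise ValueError(f"Box-Cox requires strictly positive values; "
                         f"offending indices: {bad[:10].tolist()}")


def transform(y, theta: float) -> np.ndarray:
    """Apply the power transform elementwise; continuous in theta at 0."""
    y = np.asarray(y, dtype=float)
    _check_positive(y)
    # scipy's kernel switches to the log-series form for tiny theta, which
    # keeps the transform accurate (and monotone) near theta = 0
    return special.boxcox(y, theta)


def inverse_transform(yprime, theta: float, floor: float = 1e-12) -> np.ndarray:
    """Exact inverse of :func:`transform`.

    For theta != 0 the inverse is defined only where theta*y' + 1 > 0;
    out-of-range values (possible during retrograde extrapolation) are
    clamped to ``floor`` with a warning.
    """
    yp = np.asarray(yprime, dtype=float)
    if theta == 0.0:
        return np.exp(yp)
    out_of_range = theta * yp + 1.0 <= 0
    if np.any(out_of_range):
        warnings.warn(
            f"inverse Box-Cox out of admissible range for "
            f"{int(out_of_range.sum())} value(s); clamped to {floor}",
            RuntimeWarning, stacklevel=2)
    out = special.inv_boxcox(np.where(out_of_range, np.nan, yp), theta)
    return np.where(out_of_range, floor, out)


def _profile_loglik(theta: float, y: np.ndarray) -> float:
    # normal log-likelihood of the transformed data, concentrated over
    # (mu, sigma), plus the Jacobian term (theta - 1) * sum(log y)
    return float(stats.boxcox_llf(theta, y))


def fit_theta(y, search_interval: tuple[float, float] = (-5.0, 15.0),
              fitted_on: str = "", grid_points: int = 81) -> BoxCoxModel:
    """Estimate theta by profile likelihood over ``search_interval``.

    A coarse grid locates the global basin (the profile likelihood can be
    multimodal over wide intervals); golden-section search then refines the
    best grid cell.  Requires n >= 10 strictly positive values with
    non-degenerate spread.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("fit_theta needs a 1-d sample of at least 10 values")
    _check_positive(y)
    if np.ptp(y) == 0:
        raise ValueError("constant sample: Box-Cox likelihood is flat in theta")
    lo, hi = search_interval
    if not lo < hi:
        raise ValueError("search_interval must be (lo, hi) with lo < hi")

    grid = np.linspace(lo, hi, grid_points)
    ll = np.array([_profile_loglik(t, y) for t in grid])
    i = int(np.argmax(ll))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(lambda t: -_profile_loglik(t, y),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-6})
    theta = float(res.x)
    return BoxCoxModel(theta=theta, loglik=_profile_loglik(theta, y),
                       fitted_on=fitted_on)
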