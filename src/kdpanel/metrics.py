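"""Age-stratified surveillance metrics.

Incidence and mean patient age computed from long-format case and population
panels.  The mean age of first clinical presentation is treated throughout the
package as an inverse surrogate of the force of infection, so these metrics
are the dependent variables of every downstream regression.

Two age-class schemes are used:

* a *fine* 19-class scheme (three-month classes under 2 years, six-month
  classes at 2-3 years, one-year classes thereafter, open-ended at >=10 y)
  at the resolution of the surveillance questionnaires;
* a *coarse* 11-class scheme (<1 y, ten one-year classes, open at >=10 y)
  matching the one-year resolution of census population data, onto which the
  fine classes nest exactly.

The open oldest class has no natural midpoint; its midpoint is a parameter
(default 10.5 years, with 15 years as the usual sensitivity alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeClass",
    "AgeClassScheme",
    "CasePanel",
    "PopulationPanel",
    "build_fine_scheme",
    "build_coarse_scheme",
    "aggregate_to_coarse",
    "crude_incidence",
    "age_adjusted_incidence",
    "crude_mean_age",
    "adjusted_mean_age",
    "age_category_proportions",
]

OPEN = None  # sentinel for the unbounded upper limit of the oldest class


class AgeClass(NamedTuple):
    """A contiguous age interval ``[lower, upper)`` in months of age.

    ``upper is None`` (the ``OPEN`` sentinel) marks the unbounded oldest
    class.  ``midpoint`` is in years.
    """

    label: str
    lower: int
    upper: int | None
    midpoint: float


@dataclass(frozen=True)
class AgeClassScheme:
    """An ordered, contiguous, non-overlapping set of age classes.

    Invariants are checked on construction: classes tile the age axis without
    gaps, only the last class may be open-ended, midpoints are strictly
    increasing, and every bounded class's midpoint is its interval midpoint
    converted from months to years.
    """

    classes: tuple[AgeClass, ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("scheme must contain at least one age class")
        prev_upper = 0
        mids = []
        for i, c in enumerate(self.classes):
            if c.upper is OPEN and i != len(self.classes) - 1:
                raise ValueError(f"only the last class may be open-ended, got {c.label!r}")
            if c.lower != prev_upper:
                raise ValueError(f"classes not contiguous at {c.label!r}")
            if c.upper is not OPEN:
                if c.lower >= c.upper:
                    raise ValueError(f"empty interval in class {c.label!r}")
                expected = (c.lower + c.upper) / 2.0 / 12.0
                if abs(c.midpoint - expected) > 1e-9:
                    raise ValueError(
                        f"midpoint of {c.label!r} is {c.midpoint}, expected {expected}"
                    )
                prev_upper = c.upper
            mids.append(c.midpoint)
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("midpoints must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    @property
    def midpoints(self) -> pd.Series:
        """Midpoints in years, indexed by class label."""
        return pd.Series({c.label: c.midpoint for c in self.classes}, name="midpoint")

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, label: str) -> AgeClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(label)


def _check_panel_keys(df: pd.DataFrame, scheme: AgeClassScheme, what: str) -> None:
    unknown = set(df["age_class"]) - set(scheme.labels)
    if unknown:
        raise ValueError(f"{what} uses age classes not in the scheme: {sorted(unknown)}")
    dup = df.duplicated(subset=["region", "year", "age_class"])
    if dup.any():
        rows = df.loc[dup, ["region", "year", "age_class"]].head().to_dict("records")
        raise ValueError(f"duplicate (region, year, age_class) keys in {what}: {rows}")


@dataclass
class CasePanel:
    """Long-format case counts: one row per (region, year, age_class).

    ``data`` columns: ``region``, ``year``, ``age_class``, ``count``.
    Counts are non-negative integers keyed on ``scheme``'s class labels.
    """

    data: pd.DataFrame
    scheme: AgeClassScheme

    def __post_init__(self) -> None:
        required = {"region", "year", "age_class", "count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"case panel missing columns {sorted(missing)}")
        if (self.data["count"] < 0).any():
            bad = self.data.loc[self.data["count"] < 0].head().to_dict("records")
            raise ValueError(f"negative case counts: {bad}")
        _check_panel_keys(self.data, self.scheme, "case panel")

    def totals(self) -> pd.Series:
        """Total cases per (region, year)."""
        return self.data.groupby(["region", "year"])["count"].sum()


@dataclass
class PopulationPanel:
    """Long-format population counts plus a standard age structure.

    ``data`` columns: ``region``, ``year``, ``age_class``, ``population``
    (strictly positive).  ``standard`` maps each class label of ``scheme``
    to its share S_k in the standard population; shares must sum to 1.
    """

    data: pd.DataFrame
    standard: pd.Series
    scheme: AgeClassScheme

    def __post_init__(self) -> None:
        required = {"region", "year", "age_class", "population"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"population panel missing columns {sorted(missing)}")
        if (self.data["population"] <= 0).any():
            bad = self.data.loc[self.data["population"] <= 0].head().to_dict("records")
            raise ValueError(f"non-positive populations: {bad}")
        _check_panel_keys(self.data, self.scheme, "population panel")
        s = self.standard.reindex(self.scheme.labels)
        if s.isna().any():
            raise ValueError("standard structure missing classes: "
                             f"{list(s.index[s.isna()])}")
        if abs(s.sum() - 1.0) > 1e-9:
            raise ValueError(f"standard proportions sum to {s.sum()}, expected 1")
        object.__setattr__(self, "standard", s)


# ---------------------------------------------------------------------------
# Scheme construction
# ---------------------------------------------------------------------------

_FINE_BOUNDS: list[tuple[str, int, int | None]] = [
    ("0-2m", 0, 3), ("3-5m", 3, 6), ("6-8m", 6, 9), ("9-11m", 9, 12),
    ("12-14m", 12, 15), ("15-17m", 15, 18), ("18-20m", 18, 21), ("21-23m", 21, 24),
    ("2y-2y5m", 24, 30), ("2y6m-2y11m", 30, 36),
    ("3y-3y5m", 36, 42), ("3y6m-3y11m", 42, 48),
    ("4y-4y11m", 48, 60), ("5y-5y11m", 60, 72), ("6y-6y11m", 72, 84),
    ("7y-7y11m", 84, 96), ("8y-8y11m", 96, 108), ("9y-9y11m", 108, 120),
    (">=10y", 120, OPEN),
]

_COARSE_BOUNDS: list[tuple[str, int, int | None]] = [
    ("<1y", 0, 12),
    *[(f"{a}y-{a}y11m", 12 * a, 12 * (a + 1)) for a in range(1, 10)],
    (">=10y", 120, OPEN),
]


def _build_scheme(bounds: Sequence[tuple[str, int, int | None]],
                  oldest_midpoint: float) -> AgeClassScheme:
    classes = []
    for label, lo, hi in bounds:
        mid = oldest_midpoint if hi is OPEN else (lo + hi) / 2.0 / 12.0
        classes.append(AgeClass(label, lo, hi, mid))
    return AgeClassScheme(tuple(classes))


def build_fine_scheme(oldest_midpoint: float = 10.5) -> AgeClassScheme:
    """The 19-class surveillance scheme.

    Three-month classes up to 23 months, six-month classes at ages 2 and 3,
    then one-year classes up to 9, with an open >=10 y class whose midpoint
    is ``oldest_midpoint`` years (must exceed 10).
    """
    if oldest_midpoint <= 10:
        raise ValueError("oldest_midpoint must exceed 10 years")
    return _build_scheme(_FINE_BOUNDS, oldest_midpoint)


def build_coarse_scheme(oldest_midpoint: float = 10.5) -> AgeClassScheme:
    """The 11-class census-resolution scheme: <1 y, 1..9 y, open >=10 y."""
    if oldest_midpoint <= 10:
        raise ValueError("oldest_midpoint must exceed 10 years")
    return _build_scheme(_COARSE_BOUNDS, oldest_midpoint)


def aggregate_to_coarse(cases: CasePanel,
                        oldest_midpoint: float = 10.5) -> CasePanel:
    """Sum fine 19-class counts into the coarse 11-class scheme.

    Every fine class nests inside exactly one coarse class, so totals per
    (region, year) are conserved exactly.
    """
    coarse = build_coarse_scheme(oldest_midpoint)
    mapping: dict[str, str] = {}
    for c in cases.scheme.classes:
        if c.upper is OPEN:
            target = coarse.classes[-1].label
        else:
            year_bin = c.lower // 12
            target = coarse.classes[min(year_bin, 10)].label
            tgt = coarse[target]
            if not (tgt.lower <= c.lower and (tgt.upper is OPEN or c.upper <= tgt.upper)):
                raise ValueError(f"fine class {c.label!r} does not nest in coarse scheme")
        mapping[c.label] = target
    df = cases.data.copy()
    df["age_class"] = df["age_class"].map(mapping)
    out = (df.groupby(["region", "year", "age_class"], as_index=False)["count"].sum())
    return CasePanel(out, coarse)


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------

def _under5_population(pop: PopulationPanel) -> pd.Series:
    """Population aged 0-4 years per (region, year): classes within [0, 60) months."""
    under5 = [c.label for c in pop.scheme.classes
              if c.upper is not OPEN and c.upper <= 60]
    if not under5:
        raise ValueError("population scheme has no classes within ages 0-4")
    sub = pop.data[pop.data["age_class"].isin(under5)]
    return sub.groupby(["region", "year"])["population"].sum()


def crude_incidence(cases: CasePanel, pop: PopulationPanel) -> pd.Series:
    """All-age case counts per 100,000 children aged 0-4 years.

    The numerator includes cases at *any* age; only the denominator is
    restricted to the 0-4 year population.
    """
    totals = cases.totals()
    denom = _under5_population(pop).reindex(totals.index)
    bad = denom.isna() | (denom <= 0)
    if bad.any():
        where = list(denom.index[bad][:5])
        raise ValueError(f"zero or missing 0-4 population for (region, year): {where}")
    out = 1e5 * totals / denom
    out.name = "crude_incidence"
    return out


def age_adjusted_incidence(cases: CasePanel, pop: PopulationPanel) -> pd.Series:
    """Directly standardized incidence per 100,000 (standard structure S_k).

    value = 1e5 * sum_k (N_k / P_k) * S_k over the shared age-class scheme.
    Cases and populations must be keyed on the same scheme.
    """
    if cases.scheme.labels != pop.scheme.labels:
        raise ValueError("cases and population use different age-class schemes")
    n = cases.data.set_index(["region", "year", "age_class"])["count"]
    p = pop.data.set_index(["region", "year", "age_class"])["population"]
    p_aligned = p.reindex(n.index)
    nz = n > 0
    if p_aligned[nz].isna().any():
        where = list(p_aligned.index[nz & p_aligned.isna()][:5])
        raise ValueError(f"missing class population where cases occur: {where}")
    rate = (n / p_aligned).fillna(0.0)
    s = cases.data["age_class"].map(pop.standard)
    weighted = rate.reset_index(drop=True) * s.reset_index(drop=True)
    out = weighted.groupby([cases.data["region"].reset_index(drop=True),
                            cases.data["year"].reset_index(drop=True)]).sum() * 1e5
    out.index.names = ["region", "year"]
    out.name = "age_adjusted_incidence"
    return out


# ---------------------------------------------------------------------------
# Mean patient age
# ---------------------------------------------------------------------------

def crude_mean_age(cases: CasePanel, pool_years: bool = False) -> pd.Series:
    """Case-weighted mean of age-class midpoints.

    With ``pool_years`` the age-stratified counts are first summed over all
    years within each region (one value per region), which damps seasonal
    and epidemic-year oscillations.  Region-years (or regions) with zero
    total cases yield NaN, never 0 — a mean age of nothing is undefined.
    """
    mids = cases.scheme.midpoints
    df = cases.data.copy()
    df["mx"] = df["age_class"].map(mids) * df["count"]
    keys = ["region"] if pool_years else ["region", "year"]
    g = df.groupby(keys)[["mx", "count"]].sum()
    out = g["mx"] / g["count"].where(g["count"] > 0)
    out.name = "crude_mean_age"
    return out


def adjusted_mean_age(cases: CasePanel, pop: PopulationPanel,
                      pool_years: bool = False) -> pd.Series:
    """Demography-adjusted mean patient age on the coarse scheme.

    Each class count is reweighted by S_k / C_k, where C_k is the local
    population share of class k (renormalized over the scheme) and S_k the
    standard share, removing the imprint of the local age pyramid:

        aA = sum_k M_k N_k S_k/C_k  /  sum_k N_k S_k/C_k

    When the local structure equals the standard (C == S) this reduces to
    the crude mean age.  With ``pool_years``, counts are summed and the
    population structure averaged over the period, per region.
    """
    if cases.scheme.labels != pop.scheme.labels:
        raise ValueError("cases and population use different age-class schemes")
    keys = ["region"] if pool_years else ["region", "year"]

    n = cases.data.groupby(keys + ["age_class"])["count"].sum()
    p = pop.data.groupby(keys + ["age_class"])["population"].mean()
    ptot = p.groupby(keys).sum()
    c_share = p / ptot
    c_aligned = c_share.reindex(n.index)
    nz = n > 0
    if (c_aligned[nz].isna() | (c_aligned[nz] <= 0)).any():
        bad = c_aligned[nz]
        where = list(bad.index[bad.isna() | (bad <= 0)][:5])
        raise ValueError(f"zero population share where cases occur: {where}")

    s = pd.Series(n.index.get_level_values("age_class"), index=n.index).map(pop.standard)
    w = (n * s / c_aligned).fillna(0.0)
    mids = pd.Series(n.index.get_level_values("age_class"), index=n.index).map(
        cases.scheme.midpoints)
    num = (mids * w).groupby(keys).sum()
    den = w.groupby(keys).sum()
    out = num / den.where(den > 0)
    out.name = "adjusted_mean_age"
    return out


# ---------------------------------------------------------------------------
# Age-category proportions
# ---------------------------------------------------------------------------

#: category cut-offs in months of age (lower-bound membership)
_CATEGORIES = [("pct_0_5m", 0, 6), ("pct_6m_2y", 6, 36), ("pct_3y_plus", 36, 10**9)]


def age_category_proportions(cases: CasePanel) -> pd.DataFrame:
    """Percentage of cases aged 0-5 months, 6 months-2 years, and >=3 years.

    Membership is decided by each class's lower bound; the three percentages
    sum to 100 for every (region, year) with at least one case.  Zero-case
    region-years are NaN.
    """
    def category(label: str) -> str:
        lo = cases.scheme[label].lower
        for name, a, b in _CATEGORIES:
            if a <= lo < b:
                return name
        raise AssertionError("unreachable")

    df = cases.data.copy()
    df["category"] = df["age_class"].map(category)
    counts = df.pivot_table(index=["region", "year"], columns="category",
                            values="count", aggfunc="sum", fill_value=0)
    counts = counts.reindex(columns=[c[0] for c in _CATEGORIES], fill_value=0)
    total = counts.sum(axis=1)
    pct = counts.div(total.where(total > 0), axis=0) * 100.0
    pct.columns.name = None
    return pct
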