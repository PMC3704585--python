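"""Synthetic surveillance panels with known ground truth.

Two generators share one scenario configuration:

* a *linear-panel* generator that draws the dependent variable directly from
  the random-effect AR(1) regression model at an embedded lag spec (G*, W*),
  used to validate the panel estimators by parameter recovery;
* a *mechanistic catalytic* generator in which each region-year has a force
  of infection lambda linked to the (windowed) total fertility rate, ages at
  first infection are exponential with rate lambda — so the mean age at
  infection is 1/lambda — an optional passive-immunity switch suppresses
  infections below a cut-off age, and age-class case counts are Poisson.

Covariates emulate a seven-variable prefecture panel (temperature, rainfall,
physician density, population density, aged population, higher education,
TFR): spatially autocorrelated fields on a lattice adjacency, deterministic
temporal trends, a monotonically declining TFR in expectation, and a
biennial physician series to exercise interpolation.  Population pyramids
are built from the TFR trajectory itself (cohort sizes proportional to
lagged TFR) so that crude and adjusted mean ages genuinely differ.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .cross_section import AdjacencyMatrix
from .metrics import (OPEN, AgeClassScheme, CasePanel, PopulationPanel,
                      build_coarse_scheme, build_fine_scheme)
from .panel_lag import LagSpec, lag_smooth

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "lattice_adjacency",
    "simulate_covariates",
    "simulate_linear_panel",
    "simulate_catalytic_cases",
    "mean_age_oracle",
]

#: the seven covariates of the emulated prefecture panel:
#: name -> (base level, per-year trend, spatial sd, noise sd)
_COVARIATES = {
    "temperature": (14.0, 0.02, 2.5, 0.5),
    "rainfall": (140.0, 0.1, 25.0, 10.0),
    "physician": (150.0, 2.0, 25.0, 3.0),
    "pop_density": (600.0, 2.0, 400.0, 5.0),
    "aged_population": (12.0, 0.35, 2.0, 0.2),
    "higher_education": (60.0, 0.5, 6.0, 0.5),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic study scenario; the seed is mandatory."""

    seed: int
    n_regions: int = 47
    years: tuple[int, int] = (1979, 2010)
    covariate_start: int = 1945
    oldest_midpoint: float = 10.5

    # TFR trajectory: starts near replacement, declines, regional spread,
    # and persistent region-specific wander (regions follow visibly
    # different decade-scale paths, as real prefecture fertility does --
    # this temporal structure is also what identifies the lag G)
    tfr_start: float = 2.2
    tfr_decline: float = 0.012            # per year, in expectation
    tfr_spread: float = 0.25              # between-region sd of the level
    tfr_wander_sd: float = 0.15           # stationary sd of the AR(1) wander
    tfr_wander_ar: float = 0.9            # year-to-year persistence of wander
    tfr_noise: float = 0.03               # within-region year-to-year sd
    tfr_floor: float = 0.8

    # spatial autocorrelation of covariate fields (SAR parameter on the
    # row-normalized lattice)
    spatial_rho: float = 0.5

    # force-of-infection link: lambda = a + b * windowed TFR (identity)
    # or exp(a + b * windowed TFR) (log); positive b encodes
    # sibling-driven transmission (more children -> higher hazard)
    foi_intercept: float = 0.05
    foi_slope: float = 0.35
    foi_link: str = "identity"
    foi_lag: LagSpec = field(default_factory=lambda: LagSpec(2, 1))

    # passive immunity: infections below cutoff suppressed with this prob
    passive_cutoff_months: int = 6
    passive_protect_prob: float = 0.0

    # case-count scale: expected events = cohort_size * case_fraction
    cohort_size: float = 20_000.0
    case_fraction: float = 0.01

    # linear-panel truth
    alpha: float = 10.0
    beta: float = -6.0
    phi: float = 0.5
    sigma_nu: float = 0.3
    sigma_eta: float = 0.3
    lag_spec: LagSpec = field(default_factory=lambda: LagSpec(15, 2))
    panel_covariate: str = "tfr"

    def __post_init__(self) -> None:
        if abs(self.phi) >= 1:
            raise ValueError("|phi| must be < 1")
        if self.foi_link not in ("identity", "log"):
            raise ValueError("foi_link must be 'identity' or 'log'")


@dataclass
class SyntheticTruth:
    """Generating parameters and latent quantities, enough to recompute."""

    params: dict
    lambda_: pd.Series | None = None        # (region, year) force of infection
    national: pd.DataFrame | None = None    # year -> national mean trajectories


def _region_ids(n: int) -> list[str]:
    return [f"R{i + 1:02d}" for i in range(n)]


def lattice_adjacency(n_regions: int) -> AdjacencyMatrix:
    """A near-square grid lattice over ``n_regions`` regions.

    Nodes are taken row-major from a ceil(sqrt(n)) grid, which keeps the
    subgraph connected; a stand-in for prefecture contiguity.
    """
    side = int(np.ceil(np.sqrt(n_regions)))
    g = nx.grid_2d_graph(side, side)
    nodes = [(r, c) for r in range(side) for c in range(side)][:n_regions]
    sub = g.subgraph(nodes)
    ids = _region_ids(n_regions)
    m = np.zeros((n_regions, n_regions))
    pos = {node: i for i, node in enumerate(nodes)}
    for a, b in sub.edges():
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = 1.0
    return AdjacencyMatrix(m, tuple(ids))


def _sar_field(U: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Simultaneous-autoregressive Gaussian field x = (I - rho*Wrow)^-1 e."""
    n = U.shape[0]
    e = rng.standard_normal(n)
    if rho == 0:
        return e
    deg = U.sum(axis=1)
    Wrow = U / np.where(deg > 0, deg, 1.0)[:, None]
    return np.linalg.solve(np.eye(n) - rho * Wrow, e)


def simulate_covariates(config: ScenarioConfig
                        ) -> tuple[pd.DataFrame, AdjacencyMatrix]:
    """Generate the long covariate panel and the lattice adjacency.

    Returns a DataFrame with columns region, year, variable, value spanning
    [covariate_start, years[1]].  The physician variable is emitted only on
    even calendar years (biennial survey); TFR declines in expectation and
    is floored away from zero.
    """
    rng = np.random.default_rng(config.seed)
    adj = lattice_adjacency(config.n_regions)
    ids = list(adj.regions)
    years = np.arange(config.covariate_start, config.years[1] + 1)
    y0 = years[0]
    rows = []
    for name, (base, trend, sp_sd, noise_sd) in _COVARIATES.items():
        f = _sar_field(adj.matrix, config.spatial_rho, rng)
        f = f / max(np.std(f), 1e-12) * sp_sd
        noise = rng.normal(0.0, noise_sd, size=(len(ids), len(years)))
        vals = base + f[:, None] + trend * (years - y0)[None, :] + noise
        if name == "physician":
            keep = years % 2 == 0
            vals = vals[:, keep]
            yy = years[keep]
        else:
            yy = years
        for i, r in enumerate(ids):
            rows.append(pd.DataFrame(
                {"region": r, "year": yy, "variable": name, "value": vals[i]}))
    # TFR: declining in expectation, spatially structured level, plus a
    # persistent region-specific AR(1) wander so trajectories differ in
    # shape, not just level
    f = _sar_field(adj.matrix, config.spatial_rho, rng)
    f = f / max(np.std(f), 1e-12) * config.tfr_spread
    ar, sd = config.tfr_wander_ar, config.tfr_wander_sd
    wander = np.empty((len(ids), len(years)))
    wander[:, 0] = rng.normal(0.0, sd, len(ids))
    innov_sd = sd * np.sqrt(1.0 - ar ** 2)
    for t in range(1, len(years)):
        wander[:, t] = ar * wander[:, t - 1] + rng.normal(0.0, innov_sd, len(ids))
    noise = rng.normal(0.0, config.tfr_noise, size=(len(ids), len(years)))
    tfr = (config.tfr_start + f[:, None] + wander
           - config.tfr_decline * (years - y0)[None, :] + noise)
    tfr = np.maximum(tfr, config.tfr_floor)
    for i, r in enumerate(ids):
        rows.append(pd.DataFrame(
            {"region": r, "year": years, "variable": "tfr", "value": tfr[i]}))
    panel = pd.concat(rows, ignore_index=True)
    return panel, adj


def _covariate_series(covariates: pd.DataFrame, name: str) -> pd.Series:
    sub = covariates[covariates["variable"] == name]
    if sub.empty:
        raise ValueError(f"covariate {name!r} not present")
    return sub.set_index(["region", "year"])["value"].sort_index().rename(name)


def simulate_linear_panel(config: ScenarioConfig, covariates: pd.DataFrame
                          ) -> tuple[pd.Series, SyntheticTruth]:
    """Draw Y from the random-effect AR(1) model at the embedded lag spec.

    Y_ij = alpha + beta * lag_smooth(x; G*, W*)_ij + nu_i + eps_ij with
    AR(1) eps (stationary initialization).  Raises if the covariate record
    does not cover the lag window for the first study year.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    x = _covariate_series(covariates, config.panel_covariate)
    spec = config.lag_spec
    first_needed = config.years[0] - spec.G - spec.W
    if x.index.get_level_values("year").min() > first_needed:
        raise ValueError(
            f"covariate record starts after {first_needed}, needed for the "
            f"embedded lag (G={spec.G}, W={spec.W})")
    xs = lag_smooth(x, spec.G, spec.W)
    years = np.arange(config.years[0], config.years[1] + 1)
    regions = xs.index.get_level_values("region").unique()
    idx = pd.MultiIndex.from_product([regions, years], names=["region", "year"])
    xs = xs.reindex(idx)
    if xs.isna().any():
        raise ValueError("lag window precedes covariate start for some years")

    n_r, n_t = len(regions), len(years)
    nu = rng.normal(0.0, config.sigma_nu, n_r)
    eps = np.empty((n_r, n_t))
    stat_sd = config.sigma_eta / np.sqrt(1.0 - config.phi ** 2)
    eps[:, 0] = rng.normal(0.0, stat_sd, n_r)
    for t in range(1, n_t):
        eps[:, t] = config.phi * eps[:, t - 1] + rng.normal(
            0.0, config.sigma_eta, n_r)
    y = (config.alpha + config.beta * xs.to_numpy().reshape(n_r, n_t)
         + nu[:, None] + eps)
    ys = pd.Series(y.ravel(), index=idx, name="y")
    truth = SyntheticTruth(params={
        "alpha": config.alpha, "beta": config.beta, "phi": config.phi,
        "sigma_nu": config.sigma_nu, "sigma_eta": config.sigma_eta,
        "G": spec.G, "W": spec.W, "covariate": config.panel_covariate,
        "seed": config.seed,
    })
    return ys, truth


# ---------------------------------------------------------------------------
# Catalytic (force-of-infection) generator
# ---------------------------------------------------------------------------

def mean_age_oracle(lam: float) -> float:
    """Mean age at first infection under a constant hazard: 1/lambda."""
    if lam <= 0:
        raise ValueError("force of infection must be positive")
    return 1.0 / lam


def _exp_class_mass(scheme: AgeClassScheme, lam: np.ndarray,
                    cutoff_months: int, protect: float) -> np.ndarray:
    """Exponential(lam) probability mass per age class, after suppression.

    ``lam`` is a vector of hazards; the result has shape (len(lam),
    n_classes).  Mass below ``cutoff_months`` is thinned by ``protect``;
    classes straddling the cutoff are thinned only over the sub-interval
    below it.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))[:, None]
    lo = np.array([c.lower / 12.0 for c in scheme.classes])
    hi = np.array([np.inf if c.upper is OPEN else c.upper / 12.0
                   for c in scheme.classes])
    surv_lo = np.exp(-lam * lo)
    surv_hi = np.where(np.isinf(hi), 0.0, np.exp(-lam * np.where(np.isinf(hi), 0, hi)))
    total = surv_lo - surv_hi
    if protect > 0:
        cut_y = cutoff_months / 12.0
        sub_hi = np.minimum(hi, cut_y)
        below = np.where(lo < cut_y, surv_lo - np.exp(-lam * sub_hi), 0.0)
        total = total - protect * below
    return total


def _population_pyramid(config: ScenarioConfig, tfr: pd.Series,
                        coarse: AgeClassScheme) -> pd.DataFrame:
    """Coarse-scheme populations with cohort sizes proportional to lagged TFR.

    The class of age a in year j descends from births around year j - a, so
    its size scales with TFR(j - ceil(midpoint)); the open class aggregates
    several cohorts and gets a width factor of 5 years.
    """
    base = config.cohort_size
    parts = []
    for c in coarse.classes:
        lag = int(np.ceil(c.midpoint))
        shifted_idx = pd.MultiIndex.from_arrays(
            [tfr.index.get_level_values("region"),
             tfr.index.get_level_values("year") - lag],
            names=["region", "year"])
        t_then = pd.Series(tfr.reindex(shifted_idx).to_numpy(), index=tfr.index)
        t_then = t_then.fillna(pd.Series(tfr.to_numpy(), index=tfr.index))
        width = 5.0 if c.upper is OPEN else (c.upper - c.lower) / 12.0
        part = (base * width * (t_then / 2.0)).rename("population").reset_index()
        part["age_class"] = c.label
        parts.append(part)
    return pd.concat(parts, ignore_index=True)[
        ["region", "year", "age_class", "population"]]


def simulate_catalytic_cases(config: ScenarioConfig, covariates: pd.DataFrame
                             ) -> tuple[CasePanel, PopulationPanel, SyntheticTruth]:
    """Generate age-stratified cases from a TFR-linked force of infection.

    For each region-year, lambda comes from the configured link on the
    windowed TFR; expected case counts per fine age class follow the
    exponential age-at-infection law thinned by passive immunity below the
    cut-off age, scaled to ``cohort_size * case_fraction`` events; observed
    counts are Poisson.  A coarse-scheme population panel is generated from
    the TFR trajectory, with the study-midpoint national structure as the
    standard.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    tfr = _covariate_series(covariates, "tfr")
    spec = config.foi_lag
    tfr_w = lag_smooth(tfr, spec.G, spec.W)
    years = np.arange(config.years[0], config.years[1] + 1)
    regions = tfr.index.get_level_values("region").unique()
    idx = pd.MultiIndex.from_product([regions, years], names=["region", "year"])
    tfr_w = tfr_w.reindex(idx).dropna()

    eta = config.foi_intercept + config.foi_slope * tfr_w
    lam = np.exp(eta) if config.foi_link == "log" else eta
    if (lam <= 0).any():
        bad = list(lam.index[lam <= 0][:5])
        raise ValueError(f"non-positive force of infection at {bad}")

    fine = build_fine_scheme(config.oldest_midpoint)
    coarse = build_coarse_scheme(config.oldest_midpoint)
    n_events = config.cohort_size * config.case_fraction
    labels = fine.labels
    mass = _exp_class_mass(fine, lam.to_numpy(), config.passive_cutoff_months,
                           config.passive_protect_prob)
    counts = rng.poisson(n_events * mass)  # (region-years, classes)
    ry = lam.index.to_frame(index=False)
    cases_df = pd.DataFrame({
        "region": np.repeat(ry["region"].to_numpy(), len(labels)),
        "year": np.repeat(ry["year"].to_numpy(), len(labels)),
        "age_class": np.tile(labels, len(ry)),
        "count": counts.ravel(),
    })
    cases = CasePanel(cases_df, fine)

    tfr_study = tfr.reindex(idx).dropna()
    pop_df = _population_pyramid(config, tfr_study, coarse)
    mid_year = int(np.median(years))
    nat = (pop_df[pop_df["year"] == mid_year]
           .groupby("age_class")["population"].sum())
    standard = (nat / nat.sum()).reindex(coarse.labels)
    pop = PopulationPanel(pop_df, standard, coarse)

    national = pd.DataFrame({
        "mean_lambda": lam.groupby(level="year").mean(),
        "mean_age_oracle": (1.0 / lam).groupby(level="year").mean(),
        "mean_tfr": tfr_study.groupby(level="year").mean(),
    })
    truth = SyntheticTruth(
        params={"foi_intercept": config.foi_intercept,
                "foi_slope": config.foi_slope, "foi_link": config.foi_link,
                "foi_lag": {"G": spec.G, "W": spec.W},
                "passive_cutoff_months": config.passive_cutoff_months,
                "passive_protect_prob": config.passive_protect_prob,
                "events_per_region_year": n_events, "seed": config.seed},
        lambda_=lam.rename("lambda"), national=national)
    return cases, pop, truth
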