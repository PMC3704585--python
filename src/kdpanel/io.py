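"""Readers, writers, run configuration and pipeline orchestration.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row.  Case and population panels are long-format (region, year, age_class,
count/population); covariates are long-format (region, year, variable,
value); adjacency is an edge list with an optional bridge-year tag; metric
series are written as region, year, value with missing values as empty
fields.  Every pipeline run writes its resolved configuration and a JSON
manifest beside its outputs so any file can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .backcast import reconstruct
from .cross_section import (AdjacencyMatrix, backward_eliminate,
                            build_adjacency, fit_ols, fit_spatial_lag,
                            period_means)
from .metrics import (CasePanel, PopulationPanel, adjusted_mean_age,
                      age_category_proportions, aggregate_to_coarse,
                      build_coarse_scheme, build_fine_scheme, crude_incidence,
                      crude_mean_age)
from .normalize import fit_theta, transform
from .panel_lag import (LagSpec, fit_re_ar1, grid_search_lag,
                        interpolate_biennial, lag_smooth)

__all__ = [
    "RunConfig",
    "read_case_panel", "read_population_panel", "read_covariates",
    "read_adjacency", "read_national_series",
    "write_metric_series", "read_metric_series", "write_fit_table",
    "read_panels", "run_pipeline",
]

log = logging.getLogger("kdpanel")


class RunConfig(BaseModel):
    """Validated configuration of a pipeline run."""

    # input paths (synthetic runs fill these in after generation)
    case_panel: Path | None = None
    population_panel: Path | None = None
    standard_structure: Path | None = None
    covariates: Path | None = None
    adjacency: Path | None = None
    national_series: Path | None = None

    oldest_midpoint: float = 10.5
    alpha: float = Field(0.05, gt=0, lt=1)
    g_range: tuple[int, int] = (0, 30)
    w_range: tuple[int, int] = (1, 5)
    fit_years: tuple[int, int] = (2000, 2010)
    boxcox_interval: tuple[float, float] = (-5.0, 15.0)
    normalize: bool = True
    exclude_bridges: bool = False

    run_crosssection: bool = True
    run_spatial: bool = True
    run_timeseries: bool = True
    run_reconstruct: bool = True
    reconstruct_years: tuple[int, int] = (1950, 2010)

    seed: int = 0
    outdir: Path = Path("kdpanel_out")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_csv(path: Path | str, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _bad_rows(path, df: pd.DataFrame, mask: pd.Series, what: str) -> None:
    if mask.any():
        # +2: one for the header row, one for 1-based numbering
        lines = (df.index[mask] + 2).tolist()
        raise ValueError(f"{path}: {what} at line(s) {lines[:5]}")


def read_case_panel(path, oldest_midpoint: float = 10.5,
                    fine: bool = True) -> CasePanel:
    df = _read_csv(path, {"region", "year", "age_class", "count"})
    _bad_rows(path, df, df["count"] < 0, "negative count")
    scheme = (build_fine_scheme if fine else build_coarse_scheme)(oldest_midpoint)
    panel = CasePanel(df, scheme)
    log.info("read %d case rows, %d regions, years %d-%d from %s",
             len(df), df["region"].nunique(), df["year"].min(),
             df["year"].max(), path)
    return panel


def read_population_panel(path, standard_path,
                          oldest_midpoint: float = 10.5) -> PopulationPanel:
    df = _read_csv(path, {"region", "year", "age_class", "population"})
    _bad_rows(path, df, df["population"] <= 0, "non-positive population")
    std = _read_csv(standard_path, {"age_class", "proportion"})
    standard = std.set_index("age_class")["proportion"]
    scheme = build_coarse_scheme(oldest_midpoint)
    panel = PopulationPanel(df, standard, scheme)
    log.info("read %d population rows from %s", len(df), path)
    return panel


def read_covariates(path) -> pd.DataFrame:
    df = _read_csv(path, {"region", "year", "variable", "value"})
    log.info("read %d covariate rows (%d variables) from %s",
             len(df), df["variable"].nunique(), path)
    return df


def read_adjacency(path, regions, exclude_bridges: bool = False) -> AdjacencyMatrix:
    """Edge-list CSV (region_a, region_b[, bridge_year]).

    Rows with a non-empty ``bridge_year`` mark bridge/tunnel connections;
    ``exclude_bridges`` drops them for sensitivity runs.
    """
    df = _read_csv(path, {"region_a", "region_b"})
    if exclude_bridges and "bridge_year" in df.columns:
        df = df[df["bridge_year"].isna()]
    edges = list(zip(df["region_a"], df["region_b"]))
    return build_adjacency(edges, regions)


def read_national_series(path) -> pd.Series:
    df = _read_csv(path, {"year", "value"})
    s = df.set_index("year")["value"].sort_index()
    s.index.name = "year"
    return s


def read_metric_series(path) -> pd.Series:
    df = _read_csv(path, {"region", "year", "value"})
    return df.set_index(["region", "year"])["value"]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_metric_series(series: pd.Series, path) -> None:
    out = series.rename("value").reset_index()
    out.to_csv(path, index=False, encoding="utf-8")


def write_fit_table(fit, path, extra: dict | None = None) -> None:
    """Export a CrossFit/PanelFit as rows (variable, coef, se, p, ...)."""
    df = fit.table.reset_index(names="variable")
    for key, val in (extra or {}).items():
        df[key] = val
    df.to_csv(path, index=False, encoding="utf-8")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def read_panels(config: RunConfig) -> dict:
    """Load and validate every input the enabled stages need."""
    cases = read_case_panel(config.case_panel, config.oldest_midpoint)
    pop = read_population_panel(config.population_panel,
                                config.standard_structure,
                                config.oldest_midpoint)
    cov = read_covariates(config.covariates)
    regions = sorted(cases.data["region"].unique())
    adj = None
    if config.adjacency is not None:
        adj = read_adjacency(config.adjacency, regions, config.exclude_bridges)
    national = None
    if config.national_series is not None:
        national = read_national_series(config.national_series)
    return {"cases": cases, "pop": pop, "covariates": cov,
            "adjacency": adj, "national": national, "regions": regions}


def _maybe_normalize(y: pd.Series, config: RunConfig, label: str,
                     manifest: dict) -> tuple[pd.Series, float]:
    """Box-Cox a dependent variable (or pass through when disabled)."""
    y = y.dropna()
    if not config.normalize:
        manifest["theta"][label] = None
        return y, 1.0
    model = fit_theta(y.to_numpy(), config.boxcox_interval, fitted_on=label)
    manifest["theta"][label] = model.theta
    yt = pd.Series(transform(y.to_numpy(), model.theta), index=y.index,
                   name=y.name)
    return yt, model.theta


def _pooled_incidence(cases: CasePanel, pop: PopulationPanel) -> pd.Series:
    """Period-pooled incidence: mean annual all-age cases over the
    period-averaged 0-4 population, per 100,000."""
    n_years = cases.data["year"].nunique()
    totals = cases.totals().groupby(level="region").sum() / n_years
    under5 = [c.label for c in pop.scheme.classes
              if c.upper is not None and c.upper <= 60]
    p = (pop.data[pop.data["age_class"].isin(under5)]
         .groupby(["region", "year"])["population"].sum()
         .groupby(level="region").mean())
    return (1e5 * totals / p.reindex(totals.index)).rename("pooled_incidence")


def _cross_stage(dep: pd.Series, X: pd.DataFrame, adj, config, outdir: Path,
                 label: str, manifest: dict, spatial: bool) -> None:
    common = dep.dropna().index.intersection(X.dropna().index)
    y = dep.loc[common].to_numpy()
    Xm = X.loc[common]
    rows_uni = []
    for var in Xm.columns:
        f = fit_ols(y, Xm[[var]])
        rows_uni.append({"variable": var, "coef": f.coef(var),
                         "p": float(f.table.loc[var, "p"]), "r2": f.r2,
                         "n": f.n})
    pd.DataFrame(rows_uni).to_csv(outdir / f"{label}_univariate.csv",
                                  index=False, encoding="utf-8")
    if spatial:
        fit = backward_eliminate(y, Xm, config.alpha, fit_spatial_lag, U=adj)
        extra = {"rho": fit.rho, "rho_p": fit.rho_p}
    else:
        fit = backward_eliminate(y, Xm, config.alpha, fit_ols)
        extra = {}
    write_fit_table(fit, outdir / f"{label}_multivariate.csv",
                    {"r2": fit.r2, "n": fit.n, **extra})
    manifest["stages"][label] = {
        "n": fit.n, "r2": fit.r2,
        "retained": [v for v in fit.table.index if v != "const"],
        "eliminated": fit.elimination_trace, **extra}


def _timeseries_stage(dep: pd.Series, covariates: pd.DataFrame, config,
                      outdir: Path, label: str, manifest: dict) -> dict:
    g_lo, g_hi = config.g_range
    w_lo, w_hi = config.w_range
    specs: dict[str, LagSpec] = {}
    lagged: dict[str, pd.Series] = {}
    rows_uni = []
    for var in sorted(covariates["variable"].unique()):
        x = (covariates[covariates["variable"] == var]
             .set_index(["region", "year"])["value"].sort_index().rename(var))
        yrs = x.index.get_level_values("year")
        if yrs.max() - yrs.min() + 1 > yrs.nunique():
            # survey years are not contiguous (e.g. biennial): fill 1-year gaps
            x = interpolate_biennial(x)
        spec, fit, surface = grid_search_lag(
            dep, x, range(g_lo, g_hi + 1), range(w_lo, w_hi + 1),
            config.fit_years)
        surface.to_csv(outdir / f"{label}_{var}_r2_surface.csv", index=False,
                       encoding="utf-8")
        specs[var] = spec
        lagged[var] = lag_smooth(x, spec.G, spec.W).rename(var)
        rows_uni.append({"variable": var, "G": spec.G, "W": spec.W,
                         "coef": fit.coef("x"),
                         "p": float(fit.table.loc["x", "p"]),
                         "r2": fit.overall_r2, "n": fit.n})
    uni = pd.DataFrame(rows_uni)
    uni.to_csv(outdir / f"{label}_univariate.csv", index=False,
               encoding="utf-8")

    X = pd.concat(lagged.values(), axis=1)
    years = dep.index.get_level_values("year")
    y_fit = dep[(years >= config.fit_years[0]) & (years <= config.fit_years[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        multi = backward_eliminate(y_fit, X, config.alpha, fit_re_ar1)
    write_fit_table(multi, outdir / f"{label}_multivariate.csv",
                    {"r2": getattr(multi, "overall_r2", multi.r2
                                   if hasattr(multi, "r2") else np.nan),
                     "n": multi.n})
    manifest["stages"][label] = {
        "n": multi.n,
        "specs": {v: {"G": s.G, "W": s.W} for v, s in specs.items()},
        "retained": [v for v in multi.table.index if v != "const"],
        "univariate": uni.to_dict("records"),
    }
    return {"specs": specs, "uni_fits": rows_uni, "multi": multi}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages end-to-end and write all outputs.

    Returns the JSON-serializable manifest (also written to
    ``outdir/manifest.json``).  Any stage failure aborts with the stage
    name; outputs of completed stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump(mode="json")
    (outdir / "resolved_config.json").write_text(
        json.dumps(resolved, indent=2, default=_json_default))
    cfg_hash = hashlib.sha256(
        json.dumps(resolved, sort_keys=True, default=_json_default)
        .encode()).hexdigest()[:16]
    manifest: dict = {"version": __version__, "config_hash": cfg_hash,
                      "seed": config.seed, "theta": {}, "stages": {}}
    stage = "read"
    try:
        data = read_panels(config)
        cases, pop = data["cases"], data["pop"]
        cov, adj = data["covariates"], data["adjacency"]

        stage = "metrics"
        coarse_cases = aggregate_to_coarse(cases, config.oldest_midpoint)
        inc = crude_incidence(cases, pop)
        cma = crude_mean_age(cases)
        ama = adjusted_mean_age(coarse_cases, pop)
        props = age_category_proportions(cases)
        write_metric_series(inc, outdir / "incidence.csv")
        write_metric_series(cma, outdir / "crude_mean_age.csv")
        write_metric_series(ama, outdir / "adjusted_mean_age.csv")
        props.reset_index().to_csv(outdir / "age_category_proportions.csv",
                                   index=False, encoding="utf-8")
        manifest["stages"]["metrics"] = {
            "region_years": int(inc.notna().sum()),
            "regions": len(data["regions"])}

        pooled = {
            "incidence": _pooled_incidence(cases, pop),
            "crude_mean_age": crude_mean_age(cases, pool_years=True),
            "adjusted_mean_age": adjusted_mean_age(coarse_cases, pop,
                                                   pool_years=True),
        }
        yr_span = (int(cases.data["year"].min()), int(cases.data["year"].max()))
        Xbar = period_means(cov, years=yr_span)

        if config.run_crosssection:
            stage = "crosssection"
            for label, dep in pooled.items():
                yt, _ = _maybe_normalize(dep, config, f"cross_{label}", manifest)
                _cross_stage(yt, Xbar, None, config, outdir,
                             f"cross_{label}", manifest, spatial=False)

        if config.run_spatial:
            stage = "spatial"
            if adj is None:
                raise ValueError("spatial stage enabled but no adjacency given")
            for label, dep in pooled.items():
                yt, _ = _maybe_normalize(dep, config, f"spatial_{label}",
                                         manifest)
                # align adjacency to the pooled region order
                order = [data["regions"].index(r) for r in yt.dropna().index]
                sub = adj.matrix[np.ix_(order, order)]
                _cross_stage(yt, Xbar, sub, config, outdir,
                             f"spatial_{label}", manifest, spatial=True)

        ts_results = {}
        if config.run_timeseries:
            stage = "timeseries"
            for label, dep in {"incidence": inc, "crude_mean_age": cma,
                               "adjusted_mean_age": ama}.items():
                yt, theta = _maybe_normalize(dep, config, f"ts_{label}",
                                             manifest)
                ts_results[label] = _timeseries_stage(
                    yt, cov, config, outdir, f"ts_{label}", manifest)
                ts_results[label]["theta"] = theta

        if config.run_reconstruct and data["national"] is not None \
                and "incidence" in ts_results:
            stage = "reconstruct"
            res = ts_results["incidence"]
            tfr_row = next(r for r in res["uni_fits"] if r["variable"] == "tfr")
            spec = LagSpec(tfr_row["G"], tfr_row["W"])
            x = (cov[cov["variable"] == "tfr"]
                 .set_index(["region", "year"])["value"].sort_index())
            years_dep = inc.index.get_level_values("year")
            yt, theta = _maybe_normalize(inc, config, "reconstruct_incidence",
                                         manifest)
            fit = fit_re_ar1(
                yt[(years_dep >= config.fit_years[0])
                   & (years_dep <= config.fit_years[1])],
                lag_smooth(x, spec.G, spec.W).rename("tfr"))
            lo, hi = config.reconstruct_years
            recon = reconstruct(data["national"], fit, theta, spec,
                                range(lo, hi + 1))
            out = recon.predictions.rename("predicted").reset_index()
            out.to_csv(outdir / "reconstruction_incidence.csv", index=False,
                       encoding="utf-8")
            (outdir / "reconstruction_provenance.json").write_text(
                json.dumps(recon.provenance, indent=2, default=_json_default))
            manifest["stages"]["reconstruct"] = recon.provenance
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default))
    return manifest
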