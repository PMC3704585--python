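import numpy as np
import pandas as pd
import pytest

from kdpanel.metrics import (AgeClass, AgeClassScheme, CasePanel,
                             PopulationPanel, build_fine_scheme)


def make_cases(scheme: AgeClassScheme, entries: dict) -> CasePanel:
    """entries: {(region, year): {class_label: count}}"""
    rows = []
    for (region, year), counts in entries.items():
        for label, count in counts.items():
            rows.append({"region": region, "year": year,
                         "age_class": label, "count": count})
    return CasePanel(pd.DataFrame(rows), scheme)


def make_pop(scheme: AgeClassScheme, entries: dict, standard: dict) -> PopulationPanel:
    rows = []
    for (region, year), pops in entries.items():
        for label, p in pops.items():
            rows.append({"region": region, "year": year,
                         "age_class": label, "population": p})
    return PopulationPanel(pd.DataFrame(rows), pd.Series(standard), scheme)


@pytest.fixture(scope="session")
def fine_scheme():
    return build_fine_scheme(10.5)


@pytest.fixture(scope="session")
def two_class_scheme():
    """Minimal scheme for hand-computed examples: midpoints 0.5 y and 1.5 y."""
    return AgeClassScheme((AgeClass("young", 0, 12, 0.5),
                           AgeClass("old", 12, 24, 1.5)))


@pytest.fixture(scope="session")
def small_scenario_outputs():
    """One small catalytic scenario shared across read-only tests."""
    import warnings
    from kdpanel.synthetic import ScenarioConfig, simulate_catalytic_cases, \
        simulate_covariates
    cfg = ScenarioConfig(seed=42, n_regions=16, years=(1998, 2010),
                         covariate_start=1960)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov, adj = simulate_covariates(cfg)
        cases, pop, truth = simulate_catalytic_cases(cfg, cov)
    return {"config": cfg, "covariates": cov, "adjacency": adj,
            "cases": cases, "pop": pop, "truth": truth}
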