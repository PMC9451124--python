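"""Shared fixtures: small synthetic datasets and reusable benchmark fits.

The expensive session fixtures (replicated MCMC fits) are shared across the
acceptance tests so each replicate is simulated and fitted once.
"""

from __future__ import annotations

import numpy as np
import pytest

import saesmoke as sae
from saesmoke import decompose

COV_NAMES = ("edu_low_share", "male_share")
FAST_MCMC = dict(n_chains=2, n_iter=1500, burn_in=500)


@pytest.fixture(scope="session")
def grid100():
    return sae.generate_adjacency(100, "grid", seed=1)


@pytest.fixture(scope="session")
def small_survey():
    """30-area default-condition survey with ground truth (cheap, reusable)."""
    graph = sae.generate_adjacency(30, "grid", seed=2)
    pop, truth = sae.generate_population(graph, seed=11)
    md = sae.draw_survey(pop, truth, sae.SurveyDesign(n_insample_areas=20), seed=12)
    deaths = sae.generate_mortality(pop, truth, seed=13)
    return {"graph": graph, "pop": pop, "truth": truth, "microdata": md, "deaths": deaths}


def _fit(direct_table, graph, X, seed, **kw):
    args = {**FAST_MCMC, **kw}
    return sae.BYMSmoother(seed=seed, **args).fit(
        direct_table, graph=graph, covariates=X
    )


@pytest.fixture(scope="session")
def recovery_runs(grid100):
    """Parameter-recovery benchmark: strong covariate effects, n=50 per area.

    Conditions: 100-area grid, 60 in-sample areas with ~50 analyzed
    respondents each (no missingness), true per-SD effects (-1.5, 0.8),
    sigma=0.5, phi=0.5.  Each replicate carries the covariate-adjusted fit
    and a null (intercept-only) fit on the same data.
    """
    runs = []
    design = sae.SurveyDesign(
        n_insample_areas=60, proportional_clusters=False, missingness=False
    )
    gp = sae.GenerativeParams(
        beta={"edu_low_share": -1.5, "male_share": 0.8}, sigma=0.5, phi=0.5
    )
    for rep in range(8):
        pop, truth = sae.generate_population(grid100, gp, seed=1000 + rep)
        md = sae.draw_survey(pop, truth, design, seed=2000 + rep)
        est = sae.DirectEstimator().fit(md)
        X = pop.covariate_matrix(list(COV_NAMES))
        fit_cov = _fit(est.estimates_, grid100, X, seed=rep, covariates=COV_NAMES)
        fit_null = _fit(est.estimates_, grid100, None, seed=100 + rep, covariates=())
        runs.append(
            {"truth": truth, "direct": est.estimates_, "X": X,
             "fit": fit_cov, "null": fit_null}
        )
    return runs


@pytest.fixture(scope="session")
def calibration_runs(grid100):
    """Survey-mimicking replicates at generator defaults (2-250 per area)."""
    runs = []
    for rep in range(10):
        pop, truth = sae.generate_population(grid100, sae.GenerativeParams(), seed=3000 + rep)
        md = sae.draw_survey(pop, truth, sae.SurveyDesign(n_insample_areas=60), seed=4000 + rep)
        est = sae.DirectEstimator().fit(md)
        X = pop.covariate_matrix(list(COV_NAMES))
        fit = _fit(est.estimates_, grid100, X, seed=rep, covariates=COV_NAMES)
        runs.append({"truth": truth, "direct": est.estimates_, "X": X, "fit": fit})
    return runs


@pytest.fixture(scope="session")
def sam_runs(grid100):
    """End-to-end replicates: survey -> ladder fits -> composition -> SAM."""
    runs = []
    for rep in range(3):
        pop, truth = sae.generate_population(grid100, sae.GenerativeParams(), seed=5000 + rep)
        md = sae.draw_survey(pop, truth, sae.SurveyDesign(n_insample_areas=60), seed=6000 + rep)
        deaths = sae.generate_mortality(pop, truth, seed=7000 + rep)
        X = pop.covariate_matrix(list(COV_NAMES))
        fits = {}
        for i, outc in enumerate(decompose.LADDER):
            est = sae.DirectEstimator(outcome=outc).fit(md)
            fits[outc] = _fit(
                est.estimates_, grid100, X, seed=10 * rep + i,
                covariates=COV_NAMES, n_iter=1200, burn_in=400,
            ).posterior_.p_draws
        comp = decompose.assemble_composition(fits, area_ids=grid100.area_ids)
        by_stratum = decompose.stratify_composition(
            comp, decompose.estimate_stratum_ratios(md)
        )
        runs.append(
            {
                "pop": pop, "truth": truth, "microdata": md, "deaths": deaths,
                "composition": comp, "by_stratum": by_stratum,
            }
        )
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)
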