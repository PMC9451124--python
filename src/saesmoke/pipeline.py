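"""End-to-end orchestration: simulate -> direct -> smooth -> decompose -> SAM.

Every stage derives its random seed from the master seed through a
documented ``numpy.random.SeedSequence`` spawning scheme (one child per
stage, in fixed order), logs its seed and row counts, and writes its
outputs as delimited text, so an identical config and seed reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bym, decompose, direct, io, simulate
from .config import PipelineConfig
from .paf import (
    load_relative_risks,
    sam_report,
    sam_scenario1,
    sam_scenario2,
    standard_population,
)

log = logging.getLogger("saesmoke")

_STAGES = [
    "simulate_population", "simulate_survey", "simulate_mortality",
    "fit_heavy", "fit_heavy_moderate", "fit_current", "fit_ever",
    "sam_scenario1", "sam_scenario2",
]


def stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage integer seeds (below 2^31) from the master."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(_STAGES, children)}


def _setup_logging(outdir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "pipeline.log")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns in-memory results keyed by stage.

    Writes, under ``config.outdir``: the simulated inputs (when
    simulating), per-outcome direct-estimate and smoothed-summary tables,
    composition summaries (area x category with 95% intervals), both
    attributable-mortality reports, and a diagnostics table with each
    model's DIC and per-area CPO flags.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.verbose)
    seeds = stage_seeds(config.seed)
    t0 = time.time()
    log.info("pipeline start: seed=%d outdir=%s", config.seed, outdir)

    # --- inputs: simulate or load ---
    if config.simulate is not None:
        sim = dict(config.simulate)
        n_areas = sim.pop("n_areas", 100)
        layout = sim.pop("layout", "grid")
        gp_kwargs = {k: sim.pop(k) for k in ("sigma", "phi", "mean_population") if k in sim}
        graph = simulate.generate_adjacency(n_areas, layout, seed=seeds["simulate_population"])
        params = simulate.GenerativeParams(**gp_kwargs)
        pop, truth = simulate.generate_population(
            graph, params, seed=seeds["simulate_population"]
        )
        design = simulate.SurveyDesign(**sim)
        md = simulate.draw_survey(pop, truth, design, seed=seeds["simulate_survey"])
        deaths = simulate.generate_mortality(pop, truth, seed=seeds["simulate_mortality"])
        io.write_adjacency(graph, outdir / "adjacency.gal")
        io.write_population(pop, outdir / "population.csv")
        io.write_microdata(md, outdir / "microdata.csv")
        io.write_mortality(deaths, outdir / "mortality.csv")
        io.write_truth(truth, outdir / "truth_area.csv", outdir / "truth_stratum.csv")
        log.info(
            "simulated %d areas, %d respondents, seeds=%s",
            n_areas, len(md), {k: seeds[k] for k in _STAGES[:3]},
        )
    else:
        graph = io.read_adjacency(config.inputs["adjacency"])
        pop = io.read_population(config.inputs["population"])
        md = io.read_microdata(config.inputs["microdata"])
        deaths = io.read_mortality(config.inputs["mortality"])
        truth = None
        for k, p in config.inputs.items():
            log.info("input %s: %s sha256=%s", k, p, _file_hash(p))

    covariate_names = tuple(config.model.get("covariates", ["edu_low_share", "male_share"]))
    covariates = pop.covariate_matrix(list(covariate_names))
    model_kwargs = {k: v for k, v in config.model.items() if k != "covariates"}

    # --- direct + smoothing per ladder outcome ---
    fits = {}
    direct_tables = {}
    diagnostics = []
    for outcome in config.ladder:
        t1 = time.time()
        est = direct.DirectEstimator(outcome=outcome).fit(md)
        direct_tables[outcome] = est.estimates_
        io.write_direct(est.estimates_, outdir / f"direct_{outcome}.csv")
        smoother = bym.BYMSmoother(
            covariates=covariate_names, seed=seeds[f"fit_{outcome}"], **model_kwargs
        ).fit(est.estimates_, graph=graph, covariates=covariates)
        fits[outcome] = smoother
        smoother.summary_.to_csv(outdir / f"smoothed_{outcome}.csv", index=False)
        diagnostics.append(
            {
                "outcome": outcome,
                "dic": smoother.dic_,
                "n_likelihood_areas": int((~est.estimates_["degenerate"]).sum()),
                "min_cpo": float(smoother.cpo_["cpo"].min()),
                "n_cpo_unstable": int(smoother.cpo_["unstable"].sum()),
                "max_rhat": float(np.nanmax(list(smoother.posterior_.rhat.values()))),
                "seconds": round(time.time() - t1, 2),
            }
        )
        log.info(
            "smoothed %s: DIC=%.2f seed=%d (%.1fs)",
            outcome, smoother.dic_, seeds[f"fit_{outcome}"], time.time() - t1,
        )
    pd.DataFrame(diagnostics).to_csv(outdir / "diagnostics.csv", index=False)

    # --- composition + stratification ---
    comp = decompose.assemble_composition(
        {k: fits[k].posterior_.p_draws for k in decompose.LADDER},
        area_ids=graph.area_ids,
    )
    comp_summ = decompose.composition_summaries(comp)
    comp_summ.to_csv(outdir / "composition_summaries.csv", index=False)
    ratios = decompose.estimate_stratum_ratios(md)
    comp_by_stratum = decompose.stratify_composition(comp, ratios)

    # --- attributable mortality, both scenarios ---
    rr = load_relative_risks(config.sam.get("rr_table"))
    rr_study = config.sam.get("rr_study", "shavelle")
    n_draws = int(config.sam.get("n_draws", 1000))
    std = standard_population(pop.stratum_counts().sum(axis=0))
    sam1 = sam_scenario1(
        comp_by_stratum, deaths, std, rr, rr_study=rr_study,
        n_draws=n_draws, seed=seeds["sam_scenario1"],
    )
    sam2 = sam_scenario2(
        comp_by_stratum, deaths, rr,
        rr_mapping=config.sam.get("rr_mapping", rr_study),
        n_draws=n_draws, seed=seeds["sam_scenario2"],
    )
    for est, name in ((sam1, "sam_scenario1"), (sam2, "sam_scenario2")):
        sam_report(est).to_csv(outdir / f"{name}.csv", index=False)
        est.summary().to_csv(outdir / f"{name}_summary.csv", index=False)
        log.info("%s written (n_draws=%d, seed=%d)", name, n_draws, seeds[name])

    log.info("pipeline done in %.1fs", time.time() - t0)
    return {
        "graph": graph, "population": pop, "microdata": md, "mortality": deaths,
        "truth": truth, "direct": direct_tables, "fits": fits,
        "composition": comp, "composition_by_stratum": comp_by_stratum,
        "sam1": sam1, "sam2": sam2, "diagnostics": pd.DataFrame(diagnostics),
    }
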