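"""Population attributable fractions and smoking-attributable mortality.

With exposure categories j (heavy, moderate, light, former; never smokers
are the reference at RR = 1), prevalences P_j and relative risks RR_j, the
multi-category attributable fraction is

    PAF = sum_j P_j (RR_j - 1) / ( 1 + sum_j P_j (RR_j - 1) ),

whose denominator equals ``sum over all categories of P RR`` once the
reference category (RR = 1) is included in the sum — the standard Levin
form, guaranteed to stay below 1 for finite risks.  Attributable deaths
are SAM_i = D_i * PAF_i.

Uncertainty is propagated by Monte Carlo: prevalence uncertainty through
posterior composition draws and relative-risk uncertainty through gamma
distributions moment-matched to each RR's point estimate and 95% CI
(sd = (hi - lo) / (2 * 1.96), shape = (RR/sd)^2, rate = shape/RR).

Two scenarios: scenario 1 standardizes both the smoking composition and
the death counts of every area to the national age-gender structure
(direct standardization over the six strata) before a single PAF per
area; scenario 2 computes PAF and SAM within each of the six age-gender
strata with crude stratum deaths and sums them per area.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import CATEGORIES, CategoryComposition

EXPOSED = ("heavy", "moderate", "light", "former")
STRATA = tuple(f"{a}_{g}" for a in ("15-39", "40-64", "65+") for g in ("M", "F"))


class ConfigurationError(ValueError):
    """A scenario is missing a required stratum mapping."""


@dataclass(frozen=True)
class RelativeRiskSet:
    """Relative risks for all-cause mortality by smoking category.

    One row per (study, exposure) with point estimate, 95% CI and fitted
    gamma parameters; ``categories`` may list several package categories
    sharing one published estimate (e.g. a single ">= 10 cigarettes/day"
    risk covering moderate and heavy).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if (t["rr"] <= 0).any():
            raise ValueError("relative risks must be positive")
        bad = ~((t["ci_low"] <= t["rr"]) & (t["rr"] <= t["ci_high"]))
        if bad.any():
            raise ValueError(f"CI does not bracket point estimate: {t[bad]}")

    @property
    def studies(self) -> tuple:
        return tuple(pd.unique(self.table["study"]))

    def _rows(self, study: str) -> pd.DataFrame:
        rows = self.table[self.table["study"] == study]
        if rows.empty:
            raise KeyError(f"unknown RR study {study!r}")
        return rows

    def point_estimates(self, study: str) -> dict:
        """Category -> RR point estimate for one study; never maps to 1."""
        out = {"never": 1.0}
        for _, r in self._rows(study).iterrows():
            for cat in r["categories"].split(";"):
                out[cat] = float(r["rr"])
        return out

    def gamma_params(self, study: str) -> dict:
        """Category -> (shape, rate) of the moment-matched gamma.

        A zero-width CI yields a degenerate point mass, encoded as
        (inf, inf); sampling returns the point estimate exactly.
        """
        out = {}
        for _, r in self._rows(study).iterrows():
            shape, rate = fit_gamma_rr(float(r["rr"]), (float(r["ci_low"]), float(r["ci_high"])))
            for cat in r["categories"].split(";"):
                out[cat] = (shape, rate)
        return out

    def sample(self, study: str, n_draws: int, rng: np.random.Generator) -> dict:
        """Category -> n_draws gamma samples (never fixed at 1).

        Categories sharing a published estimate share the same draws, so
        their sampling uncertainty is perfectly coupled as in the source.
        """
        draws = {"never": np.ones(n_draws)}
        for _, r in self._rows(study).iterrows():
            shape, rate = fit_gamma_rr(float(r["rr"]), (float(r["ci_low"]), float(r["ci_high"])))
            if math.isinf(shape):
                d = np.full(n_draws, float(r["rr"]))
            else:
                d = rng.gamma(shape, 1.0 / rate, size=n_draws)
            for cat in r["categories"].split(";"):
                draws[cat] = d
        return draws


def load_relative_risks(path=None) -> RelativeRiskSet:
    """Load the packaged (or a user-supplied) relative-risk table."""
    if path is None:
        ref = importlib.resources.files("saesmoke.data") / "relative_risks.csv"
        with importlib.resources.as_file(ref) as p:
            return RelativeRiskSet(pd.read_csv(p))
    return RelativeRiskSet(pd.read_csv(path))


def fit_gamma_rr(point: float, ci: tuple) -> tuple:
    """Moment-match a gamma distribution to an RR point estimate and 95% CI.

    The CI is treated as symmetric-normal on the natural scale:
    sd = (hi - lo)/(2 * 1.96); then shape = (point/sd)^2, rate = shape/point,
    so the gamma mean reproduces the point estimate exactly.  A zero-width
    CI returns (inf, inf), a point mass.
    """
    lo, hi = ci
    if not 0 < lo <= point <= hi:
        raise ValueError(f"need 0 < lo <= point <= hi, got {point} ({lo}, {hi})")
    sd = (hi - lo) / (2 * 1.959963984540054)
    if sd == 0:
        return (math.inf, math.inf)
    shape = (point / sd) ** 2
    return (shape, shape / point)


def paf(composition, rr: dict) -> float:
    """Attributable fraction for one 5-category composition.

    ``composition`` is a length-5 simplex in canonical category order
    (heavy, moderate, light, former, never) or a dict; ``rr`` maps
    categories to relative risks (never defaults to 1).
    """
    if isinstance(composition, dict):
        p = np.array([composition[c] for c in CATEGORIES], dtype=float)
    else:
        p = np.asarray(composition, dtype=float)
    if p.shape != (5,) or (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"composition is not a 5-category simplex: {p}")
    s = sum(p[CATEGORIES.index(c)] * (rr.get(c, 1.0) - 1.0) for c in EXPOSED)
    return float(s / (1.0 + s))


def _paf_draws(comp_draws: np.ndarray, rr_draws: dict) -> np.ndarray:
    """Vectorized PAF over (n_draws, n_areas, 5) compositions and RR draws."""
    s = np.zeros(comp_draws.shape[:-1])
    for j, cat in enumerate(CATEGORIES):
        if cat == "never":
            continue
        s += comp_draws[..., j] * (np.asarray(rr_draws[cat])[:, None] - 1.0)
    return s / (1.0 + s)


@dataclass(frozen=True)
class SAMEstimate:
    """Per-area PAF and attributable-death draws for one scenario.

    ``total_deaths`` is the scenario's denominator for the share of
    mortality attributable to smoking: age-gender-standardized totals in
    scenario 1, crude totals in scenario 2.
    """

    area_ids: tuple
    scenario: int
    paf_draws: np.ndarray  # (n_draws, n_areas)
    sam_draws: np.ndarray  # (n_draws, n_areas)
    total_deaths: np.ndarray  # (n_areas,)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area": self.area_ids,
                "paf_mean": self.paf_draws.mean(axis=0),
                "sam_mean": self.sam_draws.mean(axis=0),
                "sam_q2.5": np.quantile(self.sam_draws, 0.025, axis=0),
                "sam_q97.5": np.quantile(self.sam_draws, 0.975, axis=0),
                "total_deaths": self.total_deaths,
                "scenario": self.scenario,
            }
        )


def standard_population(stratum_counts: pd.Series) -> pd.Series:
    """National stratum shares from stratum person counts (sums to 1)."""
    s = stratum_counts.astype(float)
    out = s / s.sum()
    if not np.isclose(out.sum(), 1.0):
        raise ValueError("standard population shares must sum to 1")
    return out


def _aligned_stack(comp_by_stratum: dict, draw_idx: np.ndarray) -> tuple:
    strata = [s for s in STRATA if s in comp_by_stratum]
    if not strata:
        raise ValueError("no stratum compositions given")
    first = comp_by_stratum[strata[0]]
    ids = first.area_ids
    stacks = {}
    for s in strata:
        c = comp_by_stratum[s]
        if c.area_ids != ids:
            raise ValueError("stratum compositions have inconsistent area sets")
        stacks[s] = c.stack()[draw_idx]  # (n_draws, n_areas, 5)
    return ids, stacks


def sam_scenario1(
    comp_by_stratum: dict,
    deaths,
    std: pd.Series,
    rr: RelativeRiskSet,
    rr_study: str = "shavelle",
    n_draws: int = 1000,
    seed: int | None = None,
) -> SAMEstimate:
    """Scenario 1: standardize composition and deaths, then a single PAF.

    ``comp_by_stratum`` maps stratum name to an area-aligned
    :class:`~saesmoke.decompose.CategoryComposition`; ``deaths`` is a
    :class:`~saesmoke.simulate.MortalityTable` (needs stratum person
    counts); ``std`` gives the national stratum shares.  Per MC draw a
    posterior composition draw and a gamma RR draw are paired; the
    standardized death count of an area is its population times the
    std-share-weighted stratum death rates, a deterministic quantity.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_comp, rng_rr = (np.random.default_rng(s) for s in ss)
    strata = [s for s in STRATA if s in comp_by_stratum]
    missing = set(STRATA) - set(strata)
    if missing:
        raise ValueError(f"missing stratum compositions: {sorted(missing)}")
    avail = comp_by_stratum[strata[0]].n_draws
    draw_idx = rng_comp.integers(0, avail, size=n_draws)
    ids, stacks = _aligned_stack(comp_by_stratum, draw_idx)

    dt = deaths.table
    std = std.reindex(strata)
    if std.isna().any() or not np.isclose(std.sum(), 1.0):
        raise ValueError("standard population must cover all six strata and sum to 1")

    # standardized composition: std-share-weighted mean over strata
    comp_std = sum(std[s] * stacks[s] for s in strata)
    comp_std = comp_std / comp_std.sum(axis=-1, keepdims=True)

    # standardized deaths: area population x std-weighted stratum rates
    d_std = np.empty(len(ids))
    for i, area in enumerate(ids):
        rows = dt.loc[area]
        if set(strata) - set(rows.index):
            raise ValueError(f"missing stratum death rows for area {area!r}")
        rates = rows["deaths"] / rows["n_persons"].where(rows["n_persons"] > 0, np.nan)
        rates = rates.reindex(strata).fillna(0.0)
        pop = rows["n_persons"].sum()
        d_std[i] = pop * float((std * rates).sum())

    rr_draws = rr.sample(rr_study, n_draws, rng_rr)
    paf_d = _paf_draws(comp_std, rr_draws)
    return SAMEstimate(
        area_ids=ids,
        scenario=1,
        paf_draws=paf_d,
        sam_draws=paf_d * d_std[None, :],
        total_deaths=d_std,
    )


def sam_scenario2(
    comp_by_stratum: dict,
    deaths,
    rr: RelativeRiskSet,
    rr_mapping: dict | str = "shavelle",
    n_draws: int = 1000,
    seed: int | None = None,
) -> SAMEstimate:
    """Scenario 2: PAF and SAM within six age-gender strata, then summed.

    ``rr_mapping`` is a study name applied to every stratum or an explicit
    stratum -> study dict; every stratum must be mapped.  Stratum SAM uses
    crude observed stratum deaths; the area draw is the sum over strata.
    """
    if isinstance(rr_mapping, str):
        rr_mapping = {s: rr_mapping for s in STRATA}
    unmapped = set(STRATA) - set(rr_mapping)
    if unmapped:
        raise ConfigurationError(f"no RR study mapped for strata {sorted(unmapped)}")

    ss = np.random.SeedSequence(seed).spawn(2)
    rng_comp, rng_rr = (np.random.default_rng(s) for s in ss)
    strata = [s for s in STRATA if s in comp_by_stratum]
    missing = set(STRATA) - set(strata)
    if missing:
        raise ValueError(f"missing stratum compositions: {sorted(missing)}")
    avail = comp_by_stratum[strata[0]].n_draws
    draw_idx = rng_comp.integers(0, avail, size=n_draws)
    ids, stacks = _aligned_stack(comp_by_stratum, draw_idx)

    dt = deaths.table
    rr_draws_by_study = {
        study: rr.sample(study, n_draws, rng_rr)
        for study in sorted(set(rr_mapping.values()))
    }

    sam = np.zeros((n_draws, len(ids)))
    paf_num = np.zeros_like(sam)
    d_tot = np.zeros(len(ids))
    for s in strata:
        d_s = np.array([dt.loc[(area, s), "deaths"] for area in ids], dtype=float)
        paf_s = _paf_draws(stacks[s], rr_draws_by_study[rr_mapping[s]])
        sam += paf_s * d_s[None, :]
        paf_num += paf_s * d_s[None, :]
        d_tot += d_s
    with np.errstate(invalid="ignore", divide="ignore"):
        paf_area = np.where(d_tot > 0, paf_num / d_tot[None, :], 0.0)
    return SAMEstimate(
        area_ids=ids, scenario=2, paf_draws=paf_area, sam_draws=sam, total_deaths=d_tot
    )


def sam_report(est: SAMEstimate) -> pd.DataFrame:
    """Display table: deaths rounded up, with share of total mortality.

    Mirrors the headline presentation: mean attributable deaths (ceiling),
    the 95% interval bounds (also ceiling), and the attributable share of
    the scenario's total deaths (standardized for scenario 1, crude for
    scenario 2).
    """
    s = est.summary()
    out = pd.DataFrame({"area": s["area"]})
    out["sam"] = np.ceil(s["sam_mean"]).astype(int)
    out["sam_q2.5"] = np.ceil(s["sam_q2.5"]).astype(int)
    out["sam_q97.5"] = np.ceil(s["sam_q97.5"]).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(
            est.total_deaths > 0, 100.0 * s["sam_mean"] / est.total_deaths, 0.0
        )
    out["pct_of_deaths"] = pct
    out["scenario"] = est.scenario
    return out
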