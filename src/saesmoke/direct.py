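"""Design-based direct prevalence estimation per area.

Implements the weight-normalized (Hajek) ratio estimator of a binary
outcome's prevalence from complex-survey microdata, with a design variance
by cluster-level Taylor linearization under the with-replacement
first-stage approximation, and the delta-method logit transform that feeds
the spatial smoothing model.

Note on the estimator: the raw inverse-probability (Horvitz-Thompson) sum
``sum y/pi`` estimates a population *total*; prevalence requires dividing
by the estimated population size, i.e. the Hajek ratio
``sum(w y) / sum(w)``.  The Hajek form is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


class NoDataError(ValueError):
    """Raised when an area has no usable respondents for the outcome."""


class DegenerateEstimateError(ValueError):
    """Raised when a logit transform is requested for a degenerate estimate."""


#: nested binary indicators over the five smoking categories
OUTCOME_DEFS = {
    "heavy": {"heavy"},
    "heavy_moderate": {"heavy", "moderate"},
    "current": {"heavy", "moderate", "light"},
    "ever": {"heavy", "moderate", "light", "former"},
}


@dataclass
class DirectEstimate:
    """Per-area design-based prevalence with logit-scale transform.

    ``degenerate`` is set when the point estimate is 0 or 1 or the design
    variance is 0; the logit fields are NaN in that case and the area is
    excluded from the smoothing likelihood (treated like an off-sample
    area by the model).
    """

    area: object
    n_obs: int
    p_hat: float
    var_p: float
    logit_mean: float = np.nan
    logit_var: float = np.nan

    @property
    def degenerate(self) -> bool:
        return self.p_hat in (0.0, 1.0) or self.var_p == 0.0


def ht_prevalence(
    microdata: pd.DataFrame,
    area,
    outcome_def,
    weight_col: str = "ps_weight",
) -> DirectEstimate:
    """Hajek prevalence of a binary smoking indicator in one area.

    ``outcome_def`` is a set of category labels counted as the event.
    Respondents with missing smoking status are excluded.  The design
    variance is the Taylor-linearized ratio variance treating clusters
    (households) as with-replacement primary units:

        v(p) = n/(n-1) * sum_c z_c^2 / W^2,
        z_c = sum_{k in c} w_k (y_k - p),  W = sum_k w_k.

    A single-cluster area falls back to treating respondents as clusters.
    """
    rows = microdata[(microdata["area"] == area) & microdata["smoking"].notna()]
    if rows.empty:
        raise NoDataError(f"area {area!r} has no non-missing respondents")
    outcome_def = set(outcome_def)
    y = rows["smoking"].isin(outcome_def).to_numpy(dtype=float)
    w = rows[weight_col].to_numpy(dtype=float)
    wsum = w.sum()
    p = float(w @ y / wsum)

    if (rows["incl_prob"] >= 1.0).all():
        # census of the area: no sampling, no design variance
        return DirectEstimate(area=area, n_obs=len(rows), p_hat=p, var_p=0.0)
    clusters = rows["cluster"] if "cluster" in rows else pd.Series(np.arange(len(rows)))
    z = pd.Series(w * (y - p)).groupby(clusters.to_numpy()).sum().to_numpy()
    if len(z) < 2:
        z = w * (y - p)
    n_c = len(z)
    var = float(n_c / (n_c - 1) * (z**2).sum() / wsum**2) if n_c > 1 else 0.0
    return DirectEstimate(area=area, n_obs=len(rows), p_hat=p, var_p=var)


def logit_transform(est: DirectEstimate) -> DirectEstimate:
    """Populate the logit-scale mean and delta-method variance in place.

    logit_var = var_p / (p (1-p))^2.  Degenerate estimates (p in {0,1} or
    zero variance) have no finite logit representation and raise.
    """
    if est.degenerate:
        raise DegenerateEstimateError(
            f"area {est.area!r}: degenerate estimate (p={est.p_hat}, var={est.var_p})"
        )
    p = est.p_hat
    est.logit_mean = float(np.log(p / (1 - p)))
    est.logit_var = float(est.var_p / (p * (1 - p)) ** 2)
    return est


def build_direct_table(
    microdata: pd.DataFrame,
    outcome_def,
    weight_col: str = "ps_weight",
    logit_variance: str = "stabilized",
    small_counts: str = "exclude",
) -> pd.DataFrame:
    """Direct estimates for every sampled area, degenerate areas flagged.

    Returns a frame with columns area, n_obs, p_hat, var_p, logit_mean,
    logit_var, degenerate.  Areas whose respondents are all missing are
    dropped (they are off-sample as far as the outcome is concerned).

    ``logit_variance`` selects the logit-scale variance: ``"delta"`` is the
    plain delta method var_p/(p(1-p))^2; ``"stabilized"`` (default) is the
    design-effect-scaled empirical-logit form
    deff * (1/(x+1/2) + 1/(n-x+1/2)) with x = n*p_hat successes, which
    agrees with the delta method at moderate counts but avoids its severe
    upward bias when an area has only a handful of cases; ``"gvf"`` is a
    generalized-variance-function form deff / (n_i * pbar * (1-pbar))
    evaluated at the common (nationally pooled) prevalence, which breaks
    the correlation between an area's sampling noise and its likelihood
    weight — essential for rare outcomes, where precision-weighting by the
    area's own noisy count biases the smoothed level upward; ``"auto"``
    picks "gvf" when the median expected success or failure count per area
    is below 5, else "stabilized".

    ``small_counts`` controls areas whose estimate is exactly 0 or 1:
    ``"exclude"`` flags them degenerate (no likelihood contribution, the
    model imputes them spatially); ``"empirical-logit"`` replaces the
    estimate by the continuity-corrected (x+1/2)/(n+1) with an
    empirical-logit variance scaled by the median design effect of the
    well-estimated areas.  For rare outcomes (a few percent prevalence)
    exclusion zero-truncates the likelihood and biases the smoothed level
    upward, so the pipeline uses the corrected form for ladder fits.
    """
    if microdata.empty:
        raise ValueError("empty microdata")
    if logit_variance not in ("delta", "stabilized", "gvf", "auto"):
        raise ValueError(f"unknown logit_variance {logit_variance!r}")
    if small_counts not in ("exclude", "empirical-logit"):
        raise ValueError(f"unknown small_counts {small_counts!r}")
    out = []
    for area in pd.unique(microdata["area"]):
        try:
            est = ht_prevalence(microdata, area, outcome_def, weight_col)
        except NoDataError:
            continue
        if not est.degenerate:
            logit_transform(est)
        out.append(
            (est.area, est.n_obs, est.p_hat, est.var_p, est.logit_mean, est.logit_var, est.degenerate)
        )
    if not out:
        raise ValueError("no area has usable respondents")
    tab = pd.DataFrame(
        out, columns=["area", "n_obs", "p_hat", "var_p", "logit_mean", "logit_var", "degenerate"]
    )
    ok = ~tab["degenerate"]
    med_deff = (
        float((tab.var_p[ok] / (tab.p_hat[ok] * (1 - tab.p_hat[ok]) / tab.n_obs[ok])).median())
        if ok.any()
        else 1.0
    )
    if small_counts == "empirical-logit":
        boundary = tab["degenerate"] & tab["p_hat"].isin([0.0, 1.0])
        n = tab.n_obs[boundary].to_numpy(dtype=float)
        x = np.round(tab.p_hat[boundary].to_numpy() * n)
        p_t = (x + 0.5) / (n + 1.0)
        tab.loc[boundary, "p_hat"] = p_t
        tab.loc[boundary, "var_p"] = med_deff * p_t * (1 - p_t) / n
        tab.loc[boundary, "logit_mean"] = np.log(p_t / (1 - p_t))
        tab.loc[boundary, "logit_var"] = med_deff * (1 / (x + 0.5) + 1 / (n - x + 0.5))
        tab.loc[boundary, "degenerate"] = False
    live = ~tab["degenerate"]
    if logit_variance == "auto" and live.any():
        pbar = float(np.average(tab.p_hat[live], weights=tab.n_obs[live]))
        med_n = float(tab.n_obs[live].median())
        rare = min(med_n * pbar, med_n * (1 - pbar)) < 5.0
        logit_variance = "gvf" if rare else "stabilized"
    if logit_variance == "stabilized":
        # ok = rows whose variance came from their own design estimate
        n = tab.n_obs[ok].to_numpy(dtype=float)
        p = tab.p_hat[ok].to_numpy()
        x = p * n
        deff = tab.var_p[ok].to_numpy() / (p * (1 - p) / n)
        tab.loc[ok, "logit_var"] = deff * (1 / (x + 0.5) + 1 / (n - x + 0.5))
    elif logit_variance == "gvf" and live.any():
        pbar = float(np.average(tab.p_hat[live], weights=tab.n_obs[live]))
        tab.loc[live, "logit_var"] = med_deff / (tab.n_obs[live] * pbar * (1 - pbar))
    return tab


class DirectEstimator(BaseEstimator):
    """Sklearn-style wrapper around per-area Hajek estimation.

    Parameters
    ----------
    outcome : str or set
        A key of :data:`OUTCOME_DEFS` or an explicit set of category labels.
    weights : {"poststratified", "design"}
        Which weights enter the ratio; post-stratified by default.
    logit_variance : {"stabilized", "delta"}
        Logit-scale variance estimator (see :func:`build_direct_table`).

    Attributes (after ``fit``)
    --------------------------
    estimates_ : pd.DataFrame
        One row per sampled area (see :func:`build_direct_table`).
    """

    def __init__(
        self,
        outcome="current",
        weights="poststratified",
        logit_variance="auto",
        small_counts="empirical-logit",
    ):
        self.outcome = outcome
        self.weights = weights
        self.logit_variance = logit_variance
        self.small_counts = small_counts

    def fit(self, microdata: pd.DataFrame, y=None):
        outcome_def = (
            OUTCOME_DEFS[self.outcome] if isinstance(self.outcome, str) else set(self.outcome)
        )
        col = {"poststratified": "ps_weight", "design": "design_weight"}[self.weights]
        self.estimates_ = build_direct_table(
            microdata,
            outcome_def,
            weight_col=col,
            logit_variance=self.logit_variance,
            small_counts=self.small_counts,
        )
        return self

    def transform(self, microdata=None) -> pd.DataFrame:
        return self.estimates_
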