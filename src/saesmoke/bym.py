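"""Bayesian BYM2 smoothing of logit-scale direct estimates.

The observation model treats each non-degenerate in-sample area's
logit-scale direct estimate as Gaussian around the area's true logit
prevalence with known design variance:

    logit(p_hat_i) ~ N(theta_i, V_i),      theta_i = x_i' beta + b_i,

and the convolution (BYM2) random effect

    b = sigma * ( sqrt(phi) u* + sqrt(1 - phi) v ),

with u* the *scaled* intrinsic-CAR field (unit generalized variance,
sum-to-zero per connected component), v iid standard normal, sigma the
total random-effect scale and phi in [0,1] the spatial mixing fraction.
The penalized-complexity prior on sigma is exponential with rate
-log(alpha)/u (P(sigma > u) = alpha, default u=1, alpha=0.01); phi has a
uniform prior by default.  beta has a vague zero-mean Gaussian prior.

Inference is by Markov chain Monte Carlo: the joint Gaussian full
conditional of (beta, u*) given hyperparameters — with v marginalized into
the observation variance — is sampled exactly by Cholesky factorization
with sum-to-zero conditioning by kriging; (sigma, phi) move by an adaptive
random-walk Metropolis step on (log sigma, logit phi) against the
v-marginalized likelihood; v is then refreshed from its exact conditional.
Off-sample and degenerate areas carry no likelihood term, so their theta_i
draws come from the conditional of the spatial field given the sampled
neighbors — the model's "borrowing strength".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .graph import (
    AdjacencyGraph,
    scale_icar,
    scaled_icar_covariance,
    scaled_icar_precision,
)

__all__ = [
    "BYMModelSpec",
    "BYMPosterior",
    "BYMSmoother",
    "fit_bym",
    "compute_dic",
    "compute_cpo",
    "prevalence_summaries",
    "scale_icar",
]


@dataclass(frozen=True)
class BYMModelSpec:
    """Configuration of one smoothing fit (priors, covariates, MCMC)."""

    covariates: tuple = ()
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    n_chains: int = 4
    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 1
    seed: int | None = None
    fix_sigma: float | None = None
    beta_prior_var: float = 1000.0
    rhat_threshold: float = 1.05
    min_areas: int = 5

    def __post_init__(self):
        if self.pc_u <= 0:
            raise ValueError("pc_u must be > 0")
        if not 0 < self.pc_alpha < 1:
            raise ValueError("pc_alpha must be in (0, 1)")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")


@dataclass
class BYMPosterior:
    """Retained MCMC draws and observation data of a fitted model.

    Draw arrays keep an explicit chain axis ``(n_chains, n_draws, ...)``;
    the flat accessors merge chains.  ``obs_idx`` indexes the areas whose
    direct estimates entered the likelihood, aligned with ``y_obs``/``v_obs``.
    """

    area_ids: tuple
    beta: np.ndarray  # (chains, draws, p)
    sigma: np.ndarray  # (chains, draws)
    phi: np.ndarray  # (chains, draws)
    b: np.ndarray  # (chains, draws, n)
    u: np.ndarray  # (chains, draws, n) scaled-ICAR structured component
    theta: np.ndarray  # (chains, draws, n)
    loglik: np.ndarray  # (chains, draws, n_obs)
    obs_idx: np.ndarray
    y_obs: np.ndarray
    v_obs: np.ndarray
    covariate_names: tuple
    rhat: dict = field(default_factory=dict)
    accept_rate: float = np.nan

    def _flat(self, a: np.ndarray) -> np.ndarray:
        return a.reshape(-1, *a.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    @property
    def beta_draws(self) -> np.ndarray:
        return self._flat(self.beta)

    @property
    def sigma_draws(self) -> np.ndarray:
        return self._flat(self.sigma)

    @property
    def phi_draws(self) -> np.ndarray:
        return self._flat(self.phi)

    @property
    def theta_draws(self) -> np.ndarray:
        return self._flat(self.theta)

    @property
    def b_draws(self) -> np.ndarray:
        return self._flat(self.b)

    @property
    def u_draws(self) -> np.ndarray:
        return self._flat(self.u)

    @property
    def p_draws(self) -> np.ndarray:
        """Posterior prevalence draws on the probability scale, (draws, n)."""
        return expit(self.theta_draws)

    @property
    def loglik_draws(self) -> np.ndarray:
        return self._flat(self.loglik)

    @property
    def in_sample(self) -> np.ndarray:
        mask = np.zeros(len(self.area_ids), dtype=bool)
        mask[self.obs_idx] = True
        return mask


def _gaussian_loglik(y, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (y - mean) ** 2 / var)


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential-scale-reduction factor for (chains, draws)."""
    c, d = x.shape
    half = d // 2
    if half < 2:
        return np.nan
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    bvar = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + bvar / (w * n)))


def _run_chain(y, V, X, graph, spec: BYMModelSpec, rng: np.random.Generator, obs_idx):
    n = graph.n_areas
    p = X.shape[1]
    comps = graph.components()
    active_comps = [c for c in comps if len(c) > 1]
    act = np.concatenate(active_comps) if active_comps else np.array([], dtype=int)
    a = len(act)
    pos_in_act = -np.ones(n, dtype=int)
    pos_in_act[act] = np.arange(a)

    Qs = scaled_icar_precision(graph)[np.ix_(act, act)] if a else np.zeros((0, 0))
    jitter = 1e-8 * (np.trace(Qs) / a if a else 1.0)
    prior_prec = np.zeros((p + a, p + a))
    prior_prec[:p, :p] = np.eye(p) / spec.beta_prior_var
    if a:
        prior_prec[p:, p:] = Qs + jitter * np.eye(a)
    # sum-to-zero constraint rows, one per non-singleton component
    C = np.zeros((len(active_comps), p + a))
    for r, comp in enumerate(active_comps):
        C[r, p + pos_in_act[comp]] = 1.0

    Xo = X[obs_idx]
    obs_act = pos_in_act[obs_idx]  # -1 for observed areas in singleton comps
    has_u = obs_act >= 0

    lam = -np.log(spec.pc_alpha) / spec.pc_u
    sigma = spec.fix_sigma if spec.fix_sigma is not None else 0.3
    phi = 0.5
    sample_hyper = spec.fix_sigma is None
    log_s, logit_f = np.log(max(sigma, 1e-6)), 0.0
    step = 0.3
    n_acc = n_try = 0

    # marginal covariance pieces for the hyperparameter update: with beta,
    # u and v all integrated out, y ~ N(0, tau2 Xo Xo' + sigma^2 phi S +
    # (V + sigma^2 (1-phi)) I), S the constrained scaled-ICAR covariance
    n_obs = len(obs_idx)
    S_obs = scaled_icar_covariance(graph)[np.ix_(obs_idx, obs_idx)]
    XXt = spec.beta_prior_var * (Xo @ Xo.T)

    def marginal_logpost(ls, lf):
        s = np.exp(ls)
        f = expit(lf)
        cov = XXt + s**2 * f * S_obs + np.diag(V + s**2 * (1 - f))
        try:
            cf_m = linalg.cho_factor(cov, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(cf_m[0])).sum()
        quad = y @ linalg.cho_solve(cf_m, y)
        ll = -0.5 * (n_obs * np.log(2 * np.pi) + logdet + quad)
        # exp prior on sigma, uniform on phi, log-jacobians of transforms
        return ll - lam * s + ls + np.log(f) + np.log(1 - f)

    cur_lp = marginal_logpost(log_s, logit_f) if sample_hyper else None

    u_full = np.zeros(n)
    beta = np.zeros(p)

    keep = (spec.n_iter - spec.burn_in) // spec.thin
    out_beta = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_phi = np.empty(keep)
    out_b = np.empty((keep, n))
    out_u = np.empty((keep, n))
    out_theta = np.empty((keep, n))
    out_ll = np.empty((keep, len(obs_idx)))
    kpt = 0

    for it in range(spec.n_iter):
        # --- Metropolis on (log sigma, logit phi) against the marginal
        # posterior (latent field integrated out): mixes freely of the field
        if sample_hyper:
            prop_ls = log_s + step * rng.standard_normal()
            prop_lf = logit_f + step * rng.standard_normal()
            new_lp = marginal_logpost(prop_ls, prop_lf)
            n_try += 1
            if np.log(rng.uniform()) < new_lp - cur_lp:
                log_s, logit_f, cur_lp = prop_ls, prop_lf, new_lp
                n_acc += 1
            sigma, phi = float(np.exp(log_s)), float(expit(logit_f))
            if it < spec.burn_in:
                acc = n_acc / max(n_try, 1)
                step = float(
                    np.clip(step * np.exp((acc - 0.3) / np.sqrt(it + 1)), 1e-3, 5.0)
                )

        su = sigma * np.sqrt(phi)
        resid_var = V + sigma**2 * (1 - phi)
        W = 1.0 / resid_var

        # --- joint Gaussian update of (beta, u) with v marginalized ---
        P = prior_prec.copy()
        P[:p, :p] += Xo.T @ (W[:, None] * Xo)
        rhs = np.zeros(p + a)
        rhs[:p] = Xo.T @ (W * y)
        if a and su > 0:
            np.add.at(P, (p + obs_act[has_u], p + obs_act[has_u]), su**2 * W[has_u])
            cross = su * (W[has_u, None] * Xo[has_u])
            np.add.at(P[p:, :p], (obs_act[has_u],), cross)
            P[:p, p:] = P[p:, :p].T
            np.add.at(rhs, p + obs_act[has_u], su * W[has_u] * y[has_u])
        cf = linalg.cho_factor(P, lower=True)
        mean = linalg.cho_solve(cf, rhs)
        noise = linalg.solve_triangular(
            cf[0], rng.standard_normal(p + a), lower=True, trans="T"
        )
        z = mean + noise
        if a:
            K = linalg.cho_solve(cf, C.T)
            z = z - K @ np.linalg.solve(C @ K, C @ z)
        beta = z[:p]
        u_full[:] = 0.0
        if a:
            u_full[act] = z[p:]

        # --- refresh v from its exact conditional, assemble the draw ---
        v = rng.standard_normal(n)
        if sigma > 0 and phi < 1:
            sv = sigma * np.sqrt(1 - phi)
            r = y - Xo @ beta - sigma * np.sqrt(phi) * u_full[obs_idx]
            denom = V + sv**2
            v[obs_idx] = sv * r / denom + np.sqrt(V / denom) * rng.standard_normal(len(obs_idx))
        b = sigma * (np.sqrt(phi) * u_full + np.sqrt(1 - phi) * v)
        theta = X @ beta + b

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and kpt < keep:
            out_beta[kpt] = beta
            out_sigma[kpt] = sigma
            out_phi[kpt] = phi
            out_b[kpt] = b
            out_u[kpt] = u_full
            out_theta[kpt] = theta
            out_ll[kpt] = _gaussian_loglik(y, theta[obs_idx], V)
            kpt += 1

    acc_rate = n_acc / n_try if n_try else np.nan
    return out_beta, out_sigma, out_phi, out_b, out_u, out_theta, out_ll, acc_rate


def fit_bym(
    direct: pd.DataFrame,
    covariates: pd.DataFrame | None,
    graph: AdjacencyGraph,
    spec: BYMModelSpec,
) -> BYMPosterior:
    """Fit the BYM2 smoothing model to a direct-estimates table.

    ``direct`` needs columns area, logit_mean, logit_var, degenerate;
    degenerate and off-sample areas contribute no likelihood but receive
    posterior prevalence draws.  ``covariates`` is an area-indexed frame
    covering every graph area; the design matrix is an intercept plus the
    ``spec.covariates`` columns, centered across areas.
    """
    ids = graph.area_ids
    idx = graph.index
    n = len(ids)

    if spec.covariates:
        if covariates is None:
            raise ValueError("spec names covariates but no covariate table given")
        missing = set(ids) - set(covariates.index)
        if missing:
            raise ValueError(f"covariate rows missing for areas {sorted(missing)[:5]}")
        Xc = covariates.loc[list(ids), list(spec.covariates)].to_numpy(dtype=float)
        # standardize so coefficients are per-SD and comparably scaled
        Xc = Xc - Xc.mean(axis=0)
        sd = Xc.std(axis=0)
        Xc = np.divide(Xc, sd, out=np.zeros_like(Xc), where=sd > 0)
        X = np.column_stack([np.ones(n), Xc])
    else:
        X = np.ones((n, 1))

    usable = direct[
        (~direct["degenerate"])
        & np.isfinite(direct["logit_mean"])
        & (direct["logit_var"] > 0)
    ]
    usable = usable[usable["area"].isin(ids)]
    if len(usable) < spec.min_areas and spec.fix_sigma is None:
        raise ValueError(
            f"need at least {spec.min_areas} non-degenerate in-sample areas"
        )
    obs_idx = np.array([idx[a] for a in usable["area"]])
    order = np.argsort(obs_idx)
    obs_idx = obs_idx[order]
    y = usable["logit_mean"].to_numpy(dtype=float)[order]
    V = usable["logit_var"].to_numpy(dtype=float)[order]

    ss = np.random.SeedSequence(spec.seed)
    chains = [
        _run_chain(y, V, X, graph, spec, np.random.default_rng(s), obs_idx)
        for s in ss.spawn(spec.n_chains)
    ]
    post = BYMPosterior(
        area_ids=ids,
        beta=np.stack([c[0] for c in chains]),
        sigma=np.stack([c[1] for c in chains]),
        phi=np.stack([c[2] for c in chains]),
        b=np.stack([c[3] for c in chains]),
        u=np.stack([c[4] for c in chains]),
        theta=np.stack([c[5] for c in chains]),
        loglik=np.stack([c[6] for c in chains]),
        obs_idx=obs_idx,
        y_obs=y,
        v_obs=V,
        covariate_names=("intercept",) + tuple(spec.covariates),
        accept_rate=float(np.nanmean([c[7] for c in chains])),
    )
    post.rhat = {"sigma": _split_rhat(post.sigma), "phi": _split_rhat(post.phi)}
    for j, name in enumerate(post.covariate_names):
        post.rhat[f"beta_{name}"] = _split_rhat(post.beta[:, :, j])
    worst = np.nanmax(list(post.rhat.values())) if post.rhat else np.nan
    if spec.fix_sigma is None and np.isfinite(worst) and worst > spec.rhat_threshold:
        warnings.warn(
            f"MCMC may not have converged: max split-Rhat {worst:.3f} "
            f"(threshold {spec.rhat_threshold}); diagnostics: {post.rhat}",
            stacklevel=2,
        )
    return post


def compute_dic(post: BYMPosterior) -> dict:
    """Deviance information criterion from the Gaussian logit-scale likelihood.

    DIC = Dbar + p_D with p_D = Dbar - D(theta_bar); the deviance is
    -2 sum_i log N(y_i; theta_i, V_i) over likelihood areas, evaluated per
    draw (Dbar) and at the posterior mean of theta (D(theta_bar)).
    """
    dev_draws = -2.0 * post.loglik_draws.sum(axis=1)
    dbar = float(dev_draws.mean())
    theta_bar = post.theta_draws[:, post.obs_idx].mean(axis=0)
    dhat = float(-2.0 * _gaussian_loglik(post.y_obs, theta_bar, post.v_obs).sum())
    p_d = dbar - dhat
    return {"dic": dbar + p_d, "p_d": p_d, "dbar": dbar, "dhat": dhat}


def compute_cpo(post: BYMPosterior, ess_threshold: float = 0.1) -> pd.DataFrame:
    """Conditional predictive ordinates by the harmonic-mean identity.

    CPO_i = [ E_post( 1 / p(y_i | theta_i) ) ]^{-1}, estimated from
    full-posterior draws; computed in log space for stability.  The
    importance weights are 1/likelihood; areas whose normalized effective
    sample size falls below ``ess_threshold`` are flagged unstable.
    """
    ll = post.loglik_draws  # (draws, n_obs)
    m = ll.shape[0]
    neg = -ll
    mx = neg.max(axis=0)
    lse = mx + np.log(np.exp(neg - mx).sum(axis=0))
    log_cpo = np.log(m) - lse
    w = np.exp(neg - mx)
    ess = (w.sum(axis=0) ** 2) / (w**2).sum(axis=0)
    areas = [post.area_ids[i] for i in post.obs_idx]
    return pd.DataFrame(
        {
            "area": areas,
            "cpo": np.exp(log_cpo),
            "log_cpo": log_cpo,
            "ess": ess,
            "unstable": ess < ess_threshold * m,
        }
    )


def prevalence_summaries(post: BYMPosterior) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval of prevalence per area."""
    p = post.p_draws
    return pd.DataFrame(
        {
            "area": list(post.area_ids),
            "mean": p.mean(axis=0),
            "q2.5": np.quantile(p, 0.025, axis=0),
            "q97.5": np.quantile(p, 0.975, axis=0),
            "in_sample": post.in_sample,
        }
    )


class BYMSmoother(BaseEstimator):
    """Sklearn-style estimator wrapping the BYM2 smoothing fit.

    Parameters mirror :class:`BYMModelSpec`.  ``fit(direct, graph=...,
    covariates=...)`` stores the posterior and diagnostics as fitted
    attributes; ``predict`` returns per-area posterior mean prevalence.
    """

    def __init__(
        self,
        covariates=(),
        pc_u=1.0,
        pc_alpha=0.01,
        n_chains=4,
        n_iter=5000,
        burn_in=2000,
        thin=1,
        seed=None,
        fix_sigma=None,
        beta_prior_var=1000.0,
        rhat_threshold=1.05,
        min_areas=5,
    ):
        self.covariates = covariates
        self.pc_u = pc_u
        self.pc_alpha = pc_alpha
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.fix_sigma = fix_sigma
        self.beta_prior_var = beta_prior_var
        self.rhat_threshold = rhat_threshold
        self.min_areas = min_areas

    def _spec(self) -> BYMModelSpec:
        return BYMModelSpec(
            covariates=tuple(self.covariates),
            pc_u=self.pc_u,
            pc_alpha=self.pc_alpha,
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            fix_sigma=self.fix_sigma,
            beta_prior_var=self.beta_prior_var,
            rhat_threshold=self.rhat_threshold,
            min_areas=self.min_areas,
        )

    def fit(self, direct: pd.DataFrame, y=None, *, graph: AdjacencyGraph, covariates=None):
        self.posterior_ = fit_bym(direct, covariates, graph, self._spec())
        self.summary_ = prevalence_summaries(self.posterior_)
        self.dic_ = compute_dic(self.posterior_)["dic"]
        self.cpo_ = compute_cpo(self.posterior_)
        return self

    def predict(self, X=None) -> np.ndarray:
        return self.summary_["mean"].to_numpy()
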