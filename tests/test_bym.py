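"""Spatial smoothing model: conjugate and symmetry oracles, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import saesmoke as sae
from saesmoke.bym import (
    BYMModelSpec,
    BYMPosterior,
    compute_cpo,
    compute_dic,
    fit_bym,
    prevalence_summaries,
)
from saesmoke.graph import AdjacencyGraph


def direct_frame(ids, y, v, degenerate=None):
    y = np.asarray(y, dtype=float)
    deg = np.zeros(len(ids), bool) if degenerate is None else np.asarray(degenerate)
    return pd.DataFrame(
        {
            "area": ids,
            "n_obs": 50,
            "p_hat": expit(y),
            "var_p": 0.001,
            "logit_mean": y,
            "logit_var": np.asarray(v, dtype=float),
            "degenerate": deg,
        }
    )


def complete_graph(n):
    ids = [f"K{i}" for i in range(n)]
    return AdjacencyGraph.from_edges(
        ids, [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    )


def manual_posterior(theta_draws, y, v, ids, obs_idx):
    """Assemble a BYMPosterior from given theta draws (for summary/DIC tests)."""
    theta = np.asarray(theta_draws)[None, ...]  # single chain
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    n_draws, n = theta.shape[1], theta.shape[2]
    ll = -0.5 * (
        np.log(2 * np.pi * v) + (theta[:, :, obs_idx] - y) ** 2 / v
    )
    zeros = np.zeros((1, n_draws, n))
    return BYMPosterior(
        area_ids=tuple(ids),
        beta=np.zeros((1, n_draws, 1)),
        sigma=np.zeros((1, n_draws)),
        phi=np.zeros((1, n_draws)),
        b=zeros,
        u=zeros,
        theta=theta,
        loglik=ll,
        obs_idx=np.asarray(obs_idx),
        y_obs=np.asarray(y, dtype=float),
        v_obs=np.asarray(v, dtype=float),
        covariate_names=("intercept",),
    )


class TestConjugateOracle:
    def test_sigma_zero_matches_closed_form_regression(self, rng):
        """With the random effect switched off the model is Bayesian linear
        regression with known noise; MCMC moments must match the conjugate
        posterior on a 10-area instance within MC error (~1%)."""
        n = 10
        graph = sae.generate_adjacency(n, "grid")
        x = rng.standard_normal(n)
        y = -1.0 + 0.7 * x + rng.normal(0, 0.3, n)
        v = np.full(n, 0.09)
        cov = pd.DataFrame({"x": x}, index=list(graph.area_ids))
        spec = BYMModelSpec(
            covariates=("x",), fix_sigma=0.0, n_chains=2, n_iter=5000, burn_in=500, seed=9
        )
        post = fit_bym(direct_frame(graph.area_ids, y, v), cov, graph, spec)

        xs = (x - x.mean()) / x.std()
        X = np.column_stack([np.ones(n), xs])
        prec = X.T @ X / 0.09 + np.eye(2) / spec.beta_prior_var
        cov_post = np.linalg.inv(prec)
        mean_post = cov_post @ (X.T @ y / 0.09)

        got_mean = post.beta_draws.mean(axis=0)
        got_sd = post.beta_draws.std(axis=0)
        scale = np.abs(mean_post).max()
        np.testing.assert_allclose(got_mean, mean_post, atol=0.01 * scale + 3e-3)
        np.testing.assert_allclose(got_sd, np.sqrt(np.diag(cov_post)), rtol=0.05)

    def test_prior_recovery_with_uninformative_data(self):
        """Huge observation variances: the posterior of beta reverts to its
        vague zero-mean prior (mean near 0 on the prior's scale)."""
        n = 12
        graph = sae.generate_adjacency(n, "grid")
        y = np.zeros(n)
        v = np.full(n, 1e8)
        spec = BYMModelSpec(n_chains=2, n_iter=2000, burn_in=500, seed=3)
        post = fit_bym(direct_frame(graph.area_ids, y, v), None, graph, spec)
        prior_sd = np.sqrt(spec.beta_prior_var)
        assert abs(post.beta_draws.mean()) < 0.15 * prior_sd
        assert post.beta_draws.std() == pytest.approx(prior_sd, rel=0.15)


class TestStructuredComponent:
    def test_sum_to_zero_every_draw(self):
        graph = AdjacencyGraph.from_edges(
            [f"A{i}" for i in range(8)],
            [(f"A{i}", f"A{i+1}") for i in range(4)] + [("A6", "A7")],  # A5 isolated
        )
        rngy = np.random.default_rng(0)
        y = rngy.normal(-1.4, 0.5, 8)
        spec = BYMModelSpec(n_chains=2, n_iter=600, burn_in=200, seed=1)
        post = fit_bym(direct_frame(graph.area_ids, y, np.full(8, 0.1)), None, graph, spec)
        u = post.u_draws
        for comp in graph.components():
            if len(comp) > 1:
                assert np.abs(u[:, comp].sum(axis=1)).max() < 1e-8
        # singleton component carries no structured effect
        singleton = [c[0] for c in graph.components() if len(c) == 1]
        np.testing.assert_allclose(u[:, singleton], 0.0)

    def test_determinism_given_seed(self, small_survey):
        est = sae.DirectEstimator().fit(small_survey["microdata"]).estimates_
        spec = BYMModelSpec(n_chains=2, n_iter=400, burn_in=100, seed=7)
        a = fit_bym(est, None, small_survey["graph"], spec)
        b = fit_bym(est, None, small_survey["graph"], spec)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert compute_dic(a)["dic"] == compute_dic(b)["dic"]


class TestDIC:
    def test_saturated_fit_matches_hand_computation(self):
        """theta point-mass at the observations: deviance reduces to the
        log(2 pi V) normalizing term, identical in every draw, so
        DIC = Dbar = D(theta_bar)."""
        ids = list("ABCDE")
        y = np.array([-1.0, -1.2, -0.8, -1.5, -1.1])
        v = np.array([0.1, 0.2, 0.15, 0.1, 0.3])
        theta = np.tile(np.concatenate([y, [0.0]]), (200, 1))  # 6th area off-sample
        post = manual_posterior(theta, y, v, ids + ["F"], np.arange(5))
        out = compute_dic(post)
        hand = float(np.sum(np.log(2 * np.pi * v)))
        assert out["dbar"] == pytest.approx(hand)
        assert out["p_d"] == pytest.approx(0.0, abs=1e-10)
        assert out["dic"] == pytest.approx(hand)

    def test_covariate_model_improves_dic_with_true_effect(self, recovery_runs):
        wins = sum(
            compute_dic(r["fit"].posterior_)["dic"] < compute_dic(r["null"].posterior_)["dic"]
            for r in recovery_runs
        )
        assert wins >= 0.8 * len(recovery_runs)


class TestCPO:
    def test_outlier_area_has_lowest_cpo(self):
        graph = sae.generate_adjacency(16, "grid")
        rngy = np.random.default_rng(2)
        y = rngy.normal(-1.4, 0.2, 16)
        v = np.full(16, 0.05)
        y[5] += 5 * np.sqrt(v[5] + 0.04)  # shifted well away from neighbors
        spec = BYMModelSpec(n_chains=2, n_iter=1500, burn_in=500, seed=4)
        post = fit_bym(direct_frame(graph.area_ids, y, v), None, graph, spec)
        cpo = compute_cpo(post)
        assert cpo.loc[cpo.cpo.idxmin(), "area"] == graph.area_ids[5]

    def test_exchangeable_areas_get_equal_cpo(self):
        graph = complete_graph(6)
        y = np.full(6, -1.3)
        v = np.full(6, 0.2)
        spec = BYMModelSpec(n_chains=2, n_iter=3000, burn_in=500, seed=5)
        post = fit_bym(direct_frame(graph.area_ids, y, v), None, graph, spec)
        cpo = compute_cpo(post)["cpo"]
        assert cpo.max() - cpo.min() < 0.05 * cpo.mean()

    def test_unstable_estimates_flagged_by_ess(self):
        ids = list("AB")
        theta = np.random.default_rng(0).normal(0, 3, size=(400, 2))
        post = manual_posterior(theta, [0.0, 0.0], [0.01, 0.01], ids, np.arange(2))
        cpo = compute_cpo(post, ess_threshold=0.9)
        assert cpo["unstable"].all()


class TestPrevalenceSummaries:
    def test_constant_draws_give_point_interval(self):
        theta = np.zeros((100, 3))
        post = manual_posterior(theta, [0.0], [0.1], list("ABC"), np.array([0]))
        s = prevalence_summaries(post)
        assert (s["mean"] == 0.5).all()
        assert (s["q2.5"] == 0.5).all() and (s["q97.5"] == 0.5).all()

    def test_symmetric_draws_center_at_half(self, rng):
        theta = rng.standard_normal((100_000, 1))
        post = manual_posterior(theta, [0.0], [1.0], ["A"], np.array([0]))
        s = prevalence_summaries(post)
        assert s["mean"].iloc[0] == pytest.approx(0.5, abs=0.005)

    def test_summaries_monotone(self, calibration_runs):
        for r in calibration_runs[:3]:
            s = r["fit"].summary_
            assert (s["q2.5"] <= s["mean"] + 1e-12).all()
            assert (s["mean"] <= s["q97.5"] + 1e-12).all()
            assert ((s["mean"] > 0) & (s["mean"] < 1)).all()


class TestSpecValidation:
    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BYMModelSpec(pc_u=-1)
        with pytest.raises(ValueError):
            BYMModelSpec(pc_alpha=1.5)
        with pytest.raises(ValueError):
            BYMModelSpec(n_iter=100, burn_in=100)

    def test_too_few_areas_rejected(self):
        graph = sae.generate_adjacency(6, "grid")
        tab = direct_frame(graph.area_ids, np.full(6, -1.0), np.full(6, 0.1))
        tab.loc[2:, "degenerate"] = True
        with pytest.raises(ValueError, match="at least 5"):
            fit_bym(tab, None, graph, BYMModelSpec(n_iter=200, burn_in=100))

    def test_missing_covariate_rows_rejected(self):
        graph = sae.generate_adjacency(6, "grid")
        tab = direct_frame(graph.area_ids, np.full(6, -1.0), np.full(6, 0.1))
        cov = pd.DataFrame({"x": [0.0]}, index=[graph.area_ids[0]])
        with pytest.raises(ValueError, match="covariate rows missing"):
            fit_bym(tab, cov, graph, BYMModelSpec(covariates=("x",), n_iter=200, burn_in=100))

    def test_sklearn_get_set_params(self):
        sm = sae.BYMSmoother(pc_u=0.1)
        assert sm.get_params()["pc_u"] == 0.1
        sm.set_params(n_chains=1)
        assert sm.n_chains == 1


class TestPriorSensitivity:
    def test_posterior_means_robust_to_pc_prior(self, calibration_runs, grid100):
        """Refitting with the alternative prior scale (u=0.1) moves per-area
        posterior means only slightly on well-informed data."""
        r = calibration_runs[0]
        base = r["fit"].summary_["mean"].to_numpy()
        alt = sae.BYMSmoother(
            covariates=("edu_low_share", "male_share"), pc_u=0.1, pc_alpha=0.01,
            n_chains=2, n_iter=1500, burn_in=500, seed=0,
        ).fit(r["direct"], graph=grid100, covariates=r["X"])
        med_change = np.median(np.abs(alt.summary_["mean"].to_numpy() - base))
        assert med_change < 0.02
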