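"""Sampler checks: conditionals vs direct pmf sums, detailed balance on a
tiny problem, Poisson reduction, reproducibility and constraint contracts."""

import logging
import math

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from bidisperse.core_dist import MPCMPSpec, default_truncation, mpcmp_log_pmf
from bidisperse.exceptions import ConfigurationError, DataValidationError
from bidisperse.lambda_solver import solve_lambda_bisection, solve_log_lambda_many
from bidisperse.sampler import (
    MCMCConfig,
    PriorSpec,
    RegressionData,
    fitted_mean,
    highest_density_interval,
    log_cond_posterior_beta,
    log_cond_posterior_gamma,
    posterior_summary,
    run_mwg,
)
from bidisperse.synthdata import ScenarioSpec, scenario_custom


def _tiny_data(y):
    y = np.asarray(y)
    return RegressionData(y=y, X1=np.ones((len(y), 1)))


class TestRegressionData:
    def test_negative_response_rejected(self):
        with pytest.raises(DataValidationError):
            RegressionData(y=[1, -2, 0], X1=np.ones((3, 1)))

    def test_non_integer_response_rejected(self):
        with pytest.raises(DataValidationError):
            RegressionData(y=[1.5, 2.0], X1=np.ones((2, 1)))

    def test_rank_deficient_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(DataValidationError):
            RegressionData(y=[1, 2, 3, 4], X1=X)

    def test_non_contiguous_groups_rejected(self):
        with pytest.raises(DataValidationError):
            RegressionData(y=[1, 2], X1=np.eye(2), group=np.array([0, 2]))

    def test_support_bound_enforced(self):
        with pytest.raises(DataValidationError):
            RegressionData(y=[3, 12], X1=np.eye(2), support_bound=10)


class TestConditionalPosteriors:
    def test_beta_conditional_matches_single_obs_pmf(self):
        # one observation, flat-ish prior: conditional == log pmf up to the
        # factorial term (constant in beta) and the tiny prior quadratic
        data = _tiny_data([2])
        prior = PriorSpec(beta_cov=np.array([[1e12]]))
        beta = [math.log(2.5)]
        gamma = [math.log(1.5)]
        lp = log_cond_posterior_beta(beta, gamma, data, prior)
        rate = solve_lambda_bisection(2.5, 1.5)
        spec = MPCMPSpec(2.5, 1.5, default_truncation(2.5))
        direct = mpcmp_log_pmf(2, spec, rate)
        factorial_term = 1.5 * math.lgamma(3.0)
        assert lp == pytest.approx(direct + factorial_term, abs=1e-6)

    def test_beta_conditional_is_poisson_loglik_at_nu_one(self):
        rng = np.random.default_rng(3)
        X1 = np.column_stack([np.ones(40), rng.binomial(1, 0.5, 40)])
        y = rng.poisson(2.0, 40)
        data = RegressionData(y=y, X1=X1)
        prior = PriorSpec(beta_cov=1e12 * np.eye(2))
        gamma = [0.0]  # nu = 1
        b1, b2 = np.array([0.5, 0.2]), np.array([0.8, -0.1])
        diff = log_cond_posterior_beta(b1, gamma, data, prior) - log_cond_posterior_beta(
            b2, gamma, data, prior
        )
        pois_diff = poisson.logpmf(y, np.exp(X1 @ b1)).sum() - poisson.logpmf(
            y, np.exp(X1 @ b2)
        ).sum()
        assert diff == pytest.approx(pois_diff, abs=1e-6)

    def test_gamma_conditional_matches_pmf_sum(self):
        # scalar nu, small dataset: conditional == sum of log pmfs + prior
        y = np.array([0, 1, 3, 2, 1])
        data = _tiny_data(y)
        prior = PriorSpec(gamma_var=np.array([0.25]))
        beta = [math.log(1.8)]
        gamma = [math.log(1.4)]
        lp = log_cond_posterior_gamma(gamma, beta, data, prior)
        rate = solve_lambda_bisection(1.8, 1.4)
        spec = MPCMPSpec(1.8, 1.4, default_truncation(1.8))
        direct = sum(mpcmp_log_pmf(int(v), spec, rate) for v in y)
        prior_term = -0.5 * gamma[0] ** 2 / 0.25
        assert lp == pytest.approx(direct + prior_term, abs=1e-6)

    def test_gamma_conditional_factorial_term_vanishes_for_zero_counts(self):
        # log 0! = 0, so the dispersion conditional collapses to the beta
        # conditional's likelihood part
        data = _tiny_data([0, 0, 0])
        prior = PriorSpec(
            beta_cov=np.array([[1e12]]), gamma_var=np.array([1e12])
        )
        beta, gamma = [math.log(0.7)], [0.3]
        lb = log_cond_posterior_beta(beta, gamma, data, prior)
        lg = log_cond_posterior_gamma(gamma, beta, data, prior)
        assert lb == pytest.approx(lg, abs=1e-6)

    def test_gamma_conditional_consistent_under_finite_difference(self):
        # slope of the conditional agrees with an independent evaluation
        # through per-observation pmf sums at neighbouring gamma values
        y = np.array([2, 1, 4, 0, 3, 2])
        data = _tiny_data(y)
        prior = PriorSpec(gamma_var=np.array([1e12]))
        beta = [math.log(2.0)]
        h = 1e-4

        def direct(g):
            nu = math.exp(g)
            rate = solve_lambda_bisection(2.0, nu, default_truncation(2.0))
            spec = MPCMPSpec(2.0, nu, default_truncation(2.0))
            return sum(mpcmp_log_pmf(int(v), spec, rate) for v in y)

        ours = (
            log_cond_posterior_gamma([h], beta, data, prior)
            - log_cond_posterior_gamma([-h], beta, data, prior)
        ) / (2 * h)
        oracle = (direct(h) - direct(-h)) / (2 * h)
        assert ours == pytest.approx(oracle, rel=1e-4, abs=1e-4)


class TestOffset:
    def test_log2_offset_doubles_fitted_means(self):
        rng = np.random.default_rng(9)
        X1 = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = rng.poisson(2.0, 20)
        base = RegressionData(y=y, X1=X1)
        shifted = RegressionData(y=y, X1=X1, offset=np.full(20, math.log(2.0)))
        beta = np.array([0.4, 0.2])
        assert np.allclose(
            fitted_mean(shifted, beta), 2.0 * fitted_mean(base, beta)
        )


class TestRunMwg:
    def test_same_seed_reproducible(self):
        data, _ = scenario_custom(
            ScenarioSpec(
                name="tiny",
                n=60,
                beta=[0.5, 0.3],
                covariates=[("bernoulli", 0.5)],
                nu=1.2,
            ),
            seed=4,
        )
        cfg = MCMCConfig(iterations=100, warmup=50, seed=12, solver="bisection")
        a = run_mwg(data, None, cfg)
        b = run_mwg(data, None, cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.gamma, b.gamma)

    def test_identical_proposal_stream_across_solvers(self):
        # bisection and polynomial rates agree to ~1e-9, and the RNG use per
        # iteration is solver-independent, so the chains coincide
        data, _ = scenario_custom(
            ScenarioSpec(
                name="tiny",
                n=60,
                beta=[0.5, 0.3],
                covariates=[("bernoulli", 0.5)],
                nu=1.2,
            ),
            seed=4,
        )
        cfg = dict(iterations=150, warmup=50, seed=12)
        a = run_mwg(data, None, MCMCConfig(solver="bisection", **cfg))
        b = run_mwg(data, None, MCMCConfig(solver="polynomial", **cfg))
        assert np.allclose(a.beta, b.beta, atol=1e-7)
        assert np.allclose(a.gamma, b.gamma, atol=1e-7)

    def test_sum_to_zero_exact_in_every_draw(self):
        spec = ScenarioSpec(
            name="grp",
            m=4,
            per_individual=30,
            beta=[0.6, 0.2],
            covariates=[("bernoulli", 0.5)],
            theta=[-0.3, -0.1, 0.1, 0.3],
            nu=[0.9, 1.1, 1.0, 1.2],
        )
        data, _ = scenario_custom(spec, seed=2)
        cfg = MCMCConfig(
            iterations=200, warmup=100, seed=5, solver="bisection", sum_to_zero=True
        )
        chain = run_mwg(data, None, cfg)
        assert np.allclose(chain.theta.sum(axis=1), 0.0, atol=1e-12)

    def test_poisson_reduction_recovers_mle(self):
        # nu fixed at 1 turns the model into Poisson regression; the
        # posterior mean under a vague prior must sit on the GLM MLE
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        n = 2000
        X1 = np.column_stack(
            [np.ones(n), rng.binomial(1, 0.5, n), rng.binomial(1, 0.5, n)]
        )
        beta_true = np.array([0.8, 0.3, -0.4])
        y = rng.poisson(np.exp(X1 @ beta_true))
        data = RegressionData(y=y, X1=X1)
        mle = sm.GLM(y, X1, family=sm.families.Poisson()).fit().params
        cfg = MCMCConfig(
            iterations=2000, warmup=500, seed=8, solver="bisection", fix_gamma=True
        )
        chain = run_mwg(data, None, cfg)
        summ = posterior_summary(chain)
        for j in range(3):
            mcse = summ["mcse"].iloc[j]
            assert abs(chain.beta[:, j].mean() - mle[j]) < 3 * mcse + 1e-3

    def test_lookup_requires_table(self):
        data = _tiny_data([1, 2, 0])
        with pytest.raises(ConfigurationError):
            run_mwg(data, None, MCMCConfig(iterations=10, warmup=0, solver="lookup"))

    def test_posterior_matches_grid_evaluation_on_tiny_problem(self):
        # detailed-balance smoke test: intercept-only model, n = 10; the
        # sampled dispersion marginal must match dense grid integration
        rng = np.random.default_rng(77)
        rate = solve_lambda_bisection(2.0, 1.5)
        from bidisperse.core_dist import rmpcmp

        spec = MPCMPSpec(2.0, 1.5, default_truncation(2.0))
        y = rmpcmp(10, spec, rate, seed=21)
        data = _tiny_data(y)
        prior = PriorSpec(
            beta_cov=np.array([[4.0]]), gamma_var=np.array([1.0])
        )
        b_grid = np.linspace(-1.2, 2.2, 70)
        g_grid = np.linspace(-2.2, 2.2, 70)
        B, G = np.meshgrid(b_grid, g_grid, indexing="ij")
        mus, nus = np.exp(B.ravel()), np.exp(G.ravel())
        log_lam, log_G = solve_log_lambda_many(mus, nus, k=60)
        s, n = float(y.sum()), len(y)
        lfact = float(gammaln(y + 1.0).sum())
        lp = (
            s * log_lam
            - nus * lfact
            - n * log_G
            - 0.5 * B.ravel() ** 2 / 4.0
            - 0.5 * G.ravel() ** 2 / 1.0
        ).reshape(B.shape)
        post = np.exp(lp - logsumexp(lp))
        marg_gamma = post.sum(axis=0)

        cfg = MCMCConfig(iterations=40_000, warmup=2000, seed=19, solver="bisection")
        chain = run_mwg(data, prior, cfg)
        edges = np.concatenate(
            [[-np.inf], 0.5 * (g_grid[1:] + g_grid[:-1]), [np.inf]]
        )
        hist, _ = np.histogram(chain.gamma[:, 0], bins=edges)
        tv = 0.5 * np.abs(hist / hist.sum() - marg_gamma).sum()
        assert tv < 0.05


class TestPosteriorSummary:
    def test_hdi_matches_exhaustive_search_on_ten_draws(self):
        draws = np.array([0.1, 0.2, 0.25, 0.3, 0.45, 0.5, 0.55, 0.9, 1.4, 3.0])
        level = 0.7  # 7 of 10 draws
        best = (None, np.inf)
        for i in range(len(draws) - 6):
            w = draws[i + 6] - draws[i]
            if w < best[1]:
                best = ((draws[i], draws[i + 6]), w)
        assert highest_density_interval(draws, level) == best[0]

    def test_hdi_symmetric_matches_equal_tailed(self, rng):
        draws = rng.standard_normal(20_000)
        lo, hi = highest_density_interval(draws, 0.95)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.08)
        assert hi == pytest.approx(qhi, abs=0.08)

    def test_hdi_skewed_shifts_toward_mode(self, rng):
        draws = rng.exponential(1.0, 20_000)
        lo, hi = highest_density_interval(draws, 0.9)
        qlo, qhi = np.quantile(draws, [0.05, 0.95])
        assert lo < qlo
        assert hi < qhi

    def test_few_draws_warns(self, caplog):
        data, _ = scenario_custom(
            ScenarioSpec(name="t", n=40, beta=[0.4], covariates=[], nu=1.0), seed=1
        )
        cfg = MCMCConfig(iterations=50, warmup=10, seed=2, solver="bisection")
        chain = run_mwg(data, None, cfg)
        with caplog.at_level(logging.WARNING, logger="bidisperse.sampler"):
            posterior_summary(chain)
        assert any("fewer than 100" in r.message for r in caplog.records)

    def test_invalid_level_rejected(self):
        data, _ = scenario_custom(
            ScenarioSpec(name="t", n=40, beta=[0.4], covariates=[], nu=1.0), seed=1
        )
        cfg = MCMCConfig(iterations=50, warmup=10, seed=2, solver="bisection")
        chain = run_mwg(data, None, cfg)
        with pytest.raises(ConfigurationError):
            posterior_summary(chain, level=1.5)
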