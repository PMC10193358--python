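"""Distribution-level checks: limits, normalisation, moments, sampling."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from bidisperse.core_dist import (
    MPCMPSpec,
    TruncationSpec,
    default_truncation,
    log_normalising_constant,
    mpcmp_log_pmf,
    mpcmp_mean,
    mpcmp_pmf_vector,
    mpcmp_variance,
    rmpcmp,
)
from bidisperse.exceptions import InvalidArgumentError
from bidisperse.lambda_solver import solve_lambda_bisection


def brute_force_log_G(log_lam, nu, k):
    """Independent oracle: direct high-k summation with compensated addition."""
    terms = [math.exp(r * log_lam - nu * math.lgamma(r + 1)) for r in range(k + 1)]
    return math.log(math.fsum(terms))


class TestNormalisingConstant:
    def test_poisson_limit(self):
        # nu = 1: G = exp(lambda)
        val = log_normalising_constant(math.log(2.0), 1.0, TruncationSpec.series(400))
        assert val == pytest.approx(2.0, abs=1e-12)

    def test_geometric_limit(self):
        # nu = 0, lambda < 1: G = 1/(1 - lambda)
        val = log_normalising_constant(math.log(0.5), 0.0, TruncationSpec.series(400))
        assert val == pytest.approx(math.log(2.0), abs=1e-10)

    def test_matches_brute_force_summation(self):
        val = log_normalising_constant(math.log(1.5), 1.5, TruncationSpec.series(60))
        oracle = brute_force_log_G(math.log(1.5), 1.5, 500)
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_no_overflow_for_large_log_lambda(self):
        val = log_normalising_constant(50.0, 1.0, TruncationSpec.series(500))
        assert np.isfinite(val)

    @pytest.mark.parametrize("bad", [math.nan, math.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            log_normalising_constant(bad, 1.0, TruncationSpec.series(60))
        with pytest.raises(InvalidArgumentError):
            log_normalising_constant(0.0, -0.5, TruncationSpec.series(60))


class TestMean:
    def test_poisson_mean_equals_lambda(self):
        assert mpcmp_mean(math.log(3.0), 1.0, TruncationSpec.series(400)) == pytest.approx(
            3.0, abs=1e-10
        )

    def test_geometric_mean(self):
        # nu = 0: mean = lambda/(1 - lambda)
        assert mpcmp_mean(math.log(0.5), 0.0, TruncationSpec.series(400)) == pytest.approx(
            1.0, abs=1e-8
        )

    @pytest.mark.parametrize("log_lam", [math.log(0.7), math.log(2.0), math.log(5.0)])
    def test_mean_is_dlogG_dloglambda(self, log_lam):
        # the mean equals the derivative of log G w.r.t. log lambda
        trunc = TruncationSpec.series(200)
        h = 1e-6
        fd = (
            log_normalising_constant(log_lam + h, 1.5, trunc)
            - log_normalising_constant(log_lam - h, 1.5, trunc)
        ) / (2 * h)
        assert mpcmp_mean(log_lam, 1.5, trunc) == pytest.approx(fd, rel=1e-6)


class TestPmf:
    def test_reduces_to_poisson_at_nu_one(self):
        rate = solve_lambda_bisection(4.0, 1.0, tol=1e-14)
        spec = MPCMPSpec(4.0, 1.0, default_truncation(4.0))
        for y in range(31):
            assert mpcmp_log_pmf(y, spec, rate) == pytest.approx(
                poisson.logpmf(y, 4.0), abs=1e-10
            )

    @pytest.mark.parametrize("mu", [0.5, 2.0, 8.0, 20.0])
    @pytest.mark.parametrize("nu", [0.25, 1.0, 1.5, 4.0])
    def test_normalisation_on_grid(self, mu, nu):
        rate = solve_lambda_bisection(mu, nu)
        spec = MPCMPSpec(mu, nu, default_truncation(mu))
        assert mpcmp_pmf_vector(spec, rate).sum() == pytest.approx(1.0, abs=1e-10)

    def test_mean_constraint_through_solver(self):
        rate = solve_lambda_bisection(2.5, 1.5)
        spec = MPCMPSpec(2.5, 1.5, default_truncation(2.5))
        pmf = mpcmp_pmf_vector(spec, rate)
        assert pmf @ np.arange(len(pmf)) == pytest.approx(2.5, abs=1e-6)

    def test_hard_bound_rejects_out_of_support(self):
        spec = MPCMPSpec(2.0, 1.0, TruncationSpec.bound(10))
        rate = solve_lambda_bisection(2.0, 1.0, TruncationSpec.bound(10))
        with pytest.raises(InvalidArgumentError):
            mpcmp_log_pmf(11, spec, rate)

    def test_negative_y_rejected(self):
        rate = solve_lambda_bisection(2.0, 1.0)
        with pytest.raises(InvalidArgumentError):
            mpcmp_log_pmf(-1, MPCMPSpec(2.0, 1.0), rate)

    def test_mu_zero_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MPCMPSpec(0.0, 1.0)


class TestVariance:
    def test_poisson_variance_equals_mean(self):
        rate = solve_lambda_bisection(4.0, 1.0)
        assert mpcmp_variance(MPCMPSpec(4.0, 1.0), rate) == pytest.approx(4.0, abs=1e-8)

    @pytest.mark.parametrize(
        "nu,relation", [(1.5, "under"), (0.8, "over"), (1.0, "equal")]
    )
    def test_dispersion_ordering(self, nu, relation):
        rate = solve_lambda_bisection(4.0, nu)
        var = mpcmp_variance(MPCMPSpec(4.0, nu), rate)
        if relation == "under":
            assert var < 4.0 - 1e-6
        elif relation == "over":
            assert var > 4.0 + 1e-6
        else:
            assert var == pytest.approx(4.0, abs=1e-6)

    def test_matches_direct_moment_sum(self):
        rate = solve_lambda_bisection(4.0, 0.8)
        spec = MPCMPSpec(4.0, 0.8, default_truncation(4.0))
        pmf = mpcmp_pmf_vector(spec, rate)
        r = np.arange(len(pmf))
        oracle = pmf @ (r**2) - (pmf @ r) ** 2
        assert mpcmp_variance(spec, rate) == pytest.approx(oracle, rel=1e-12)


class TestTruncationRobustness:
    def test_k60_vs_k90_in_low_count_regime(self):
        # results are insensitive to the series length once k ~ 2 mu_max,
        # in the moderate-mean moderate-dispersion regime of count data
        from bidisperse.lambda_solver import solve_log_lambda_many

        mus = np.linspace(0.5, 16.0, 20)
        nus = np.linspace(0.5, 4.0, 10)

        MU, NU = np.meshgrid(mus, nus)
        l60, _ = solve_log_lambda_many(MU.ravel(), NU.ravel(), k=60)
        l90, _ = solve_log_lambda_many(MU.ravel(), NU.ravel(), k=90)
        assert np.max(np.abs(l60 - l90)) < 1e-8


class TestSampling:
    def test_same_seed_identical(self):
        rate = solve_lambda_bisection(3.0, 1.5)
        spec = MPCMPSpec(3.0, 1.5, default_truncation(3.0))
        a = rmpcmp(1000, spec, rate, seed=11)
        b = rmpcmp(1000, spec, rate, seed=11)
        assert np.array_equal(a, b)

    def test_sample_mean_within_clt_bound(self):
        n = 200_000
        rate = solve_lambda_bisection(3.0, 1.5)
        spec = MPCMPSpec(3.0, 1.5, default_truncation(3.0))
        draws = rmpcmp(n, spec, rate, seed=5)
        se = math.sqrt(mpcmp_variance(spec, rate) / n)
        assert abs(draws.mean() - 3.0) < 4 * se

    def test_poisson_goodness_of_fit(self):
        n = 200_000
        rate = solve_lambda_bisection(3.0, 1.0)
        spec = MPCMPSpec(3.0, 1.0, default_truncation(3.0))
        draws = rmpcmp(n, spec, rate, seed=6)
        hi = 12
        obs = np.bincount(np.minimum(draws, hi), minlength=hi + 1)
        probs = poisson.pmf(np.arange(hi), 3.0)
        probs = np.append(probs, 1.0 - probs.sum())
        stat, pval = chisquare(obs, n * probs)
        assert pval > 0.001
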