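"""Metropolis-within-Gibbs inference for MPCMP regression models.

The model is log-linear in both components:

    log mu_i = x1_i' beta + offset_i + theta_{g(i)},
    log nu_i = x2_i' gamma,

with ``theta`` optional individual (group-level) effects on the mean and
``gamma`` the dispersion coefficients -- when ``X2`` is the group indicator
matrix, ``gamma`` is the vector of individual log-dispersions ``alpha_i``.
The posterior conditionals (up to additive constants) are

    log pi(beta | gamma, y)  =  log pi(beta)  + sum_i [ y_i log lambda_i - log G_i ],
    log pi(gamma | beta, y)  =  log pi(gamma) + sum_i [ y_i log lambda_i - log G_i
                                                        - nu_i log(y_i!) ],

where ``lambda_i = lambda(mu_i, nu_i)`` must be recovered from the mean
constraint at every evaluation -- by bisection/Newton, polynomial root
extraction, or the interpolated look-up table (the pluggable solver that
this package exists to compare).

Updates: ``beta`` as one multivariate-normal random-walk block, ``theta``
as a block (optionally reparameterised to satisfy an exact sum-to-zero
constraint), and each ``gamma`` component by a scalar normal random walk on
the log-dispersion scale.  Proposal scales are Robbins-Monro adapted during
warmup (targets 0.234 for blocks, 0.44 for scalars) and frozen afterwards
so detailed balance holds for every retained draw.  The random-number
stream consumed per iteration is identical whatever the rate solver, so
chains run with different solvers share their proposal noise exactly.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_dist import BOUND, SERIES, moments
from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    DataValidationError,
    SamplerError,
)
from .lambda_solver import solve_lambda_polynomial, solve_log_lambda_many

__all__ = [
    "RegressionData",
    "PriorSpec",
    "MCMCConfig",
    "ChainResult",
    "log_cond_posterior_beta",
    "log_cond_posterior_gamma",
    "run_mwg",
    "run_chains",
    "posterior_summary",
    "fitted_mean",
    "split_rhat",
    "effective_sample_size",
]

logger = logging.getLogger(__name__)


# -- data containers -------------------------------------------------------


@dataclass
class RegressionData:
    """Responses plus design matrices for the mean and dispersion components."""

    y: np.ndarray
    X1: np.ndarray
    X2: Optional[np.ndarray] = None
    group: Optional[np.ndarray] = None
    offset: Optional[np.ndarray] = None
    support_bound: Optional[int] = None
    x1_names: Optional[list] = None
    x2_names: Optional[list] = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if not np.issubdtype(self.y.dtype, np.integer):
            if np.any(self.y != np.round(self.y)):
                raise DataValidationError("responses must be integers")
            self.y = self.y.astype(np.int64)
        if np.any(self.y < 0):
            raise DataValidationError("responses must be non-negative")
        self.X1 = np.asarray(self.X1, dtype=float)
        n = len(self.y)
        if self.X1.shape[0] != n:
            raise DataValidationError("X1 row count does not match y")
        if self.X2 is None:
            self.X2 = np.ones((n, 1))
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X2.shape[0] != n:
            raise DataValidationError("X2 row count does not match y")
        for name, X in (("X1", self.X1), ("X2", self.X2)):
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise DataValidationError(f"{name} is rank deficient")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != n:
                raise DataValidationError("group length does not match y")
            levels = np.unique(self.group)
            if not np.array_equal(levels, np.arange(len(levels))):
                raise DataValidationError("group labels must be contiguous 0..m-1")
        if self.offset is not None:
            self.offset = np.asarray(self.offset, dtype=float)
            if self.offset.shape[0] != n:
                raise DataValidationError("offset length does not match y")
        if self.support_bound is not None:
            if np.any(self.y > self.support_bound):
                raise DataValidationError("responses exceed the declared support bound")
        if self.x1_names is None:
            self.x1_names = [f"beta[{j}]" for j in range(self.p)]
        if self.x2_names is None:
            self.x2_names = [f"gamma[{j}]" for j in range(self.q)]

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X1.shape[1]

    @property
    def q(self) -> int:
        return self.X2.shape[1]

    @property
    def m(self) -> int:
        return 0 if self.group is None else int(self.group.max()) + 1


@dataclass
class PriorSpec:
    """Independent normal priors for ``beta``, ``theta`` and ``gamma``.

    Defaults are deliberately vague for the mean coefficients
    (``beta ~ N(0, 1e5 I)``, the log-normal ``nu`` prior translating to
    ``gamma ~ N(0, 1e5)`` for a scalar dispersion) and weakly informative
    for individual effects (``theta ~ N(0, 0.5 log 2 I)``, dispersion
    ``alpha_i ~ N(0, 0.25)``), mirroring common practice for count models
    where individual rates are unlikely to double or halve.
    """

    beta_mean: np.ndarray = None
    beta_cov: np.ndarray = None
    theta_mean: np.ndarray = None
    theta_cov: np.ndarray = None
    gamma_mean: np.ndarray = None
    gamma_var: np.ndarray = None

    @classmethod
    def default(cls, data: RegressionData) -> "PriorSpec":
        p, q, m = data.p, data.q, data.m
        scalar_dispersion = q == 1 and np.all(data.X2 == 1.0)
        gamma_var = np.full(q, 1e5 if scalar_dispersion else 0.25)
        spec = cls(
            beta_mean=np.zeros(p),
            beta_cov=1e5 * np.eye(p),
            theta_mean=np.zeros(m) if m else None,
            theta_cov=0.5 * math.log(2) * np.eye(m) if m else None,
            gamma_mean=np.zeros(q),
            gamma_var=gamma_var,
        )
        return spec

    def validated(self, data: RegressionData) -> "PriorSpec":
        out = PriorSpec.default(data)
        for name in ("beta_mean", "beta_cov", "theta_mean", "theta_cov", "gamma_mean", "gamma_var"):
            val = getattr(self, name)
            if val is not None:
                setattr(out, name, np.asarray(val, dtype=float))
        for covname in ("beta_cov", "theta_cov"):
            cov = getattr(out, covname)
            if cov is not None:
                if not np.allclose(cov, cov.T):
                    raise ConfigurationError(f"{covname} must be symmetric")
                if np.any(np.linalg.eigvalsh(cov) <= 0):
                    raise ConfigurationError(f"{covname} must be positive definite")
        return out


@dataclass
class MCMCConfig:
    """Run-length, seed, solver and proposal settings for one chain."""

    iterations: int = 5000
    warmup: int = 1000
    seed: int = 0
    solver: str = "lookup"
    thin: int = 1
    sum_to_zero: bool = True
    adapt: bool = True
    k: Optional[int] = None
    tol: float = 1e-10
    fix_gamma: bool = False
    beta_proposal_cov: Optional[np.ndarray] = None
    theta_proposal_scale: float = 0.1
    gamma_proposal_scale: float = 0.1

    def __post_init__(self):
        if not self.iterations > 0:
            raise ConfigurationError("iterations must be positive")
        if self.warmup < 0:
            raise ConfigurationError("warmup must be non-negative")
        if self.solver not in ("lookup", "bisection", "polynomial"):
            raise ConfigurationError(f"unknown solver {self.solver!r}")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")


@dataclass
class ChainResult:
    """Retained draws plus acceptance and timing traces for one chain."""

    beta: np.ndarray
    gamma: np.ndarray
    theta: Optional[np.ndarray]
    accept_rates: dict
    iter_times: np.ndarray
    warmup_times: np.ndarray
    config: MCMCConfig
    param_names: list
    table: object = None
    table_build_time: float = 0.0
    proposal_scales: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def draws_matrix(self) -> np.ndarray:
        cols = [self.beta, self.gamma]
        if self.theta is not None:
            cols.append(self.theta)
        return np.column_stack(cols)


# -- likelihood machinery --------------------------------------------------


def fitted_mean(data: RegressionData, beta, theta=None) -> np.ndarray:
    """Per-observation mean ``exp(x1' beta + offset + theta_g)``."""
    eta = data.X1 @ np.asarray(beta, dtype=float)
    if data.offset is not None:
        eta = eta + data.offset
    if theta is not None and data.group is not None:
        eta = eta + np.asarray(theta, dtype=float)[data.group]
    return np.exp(eta)


class _Evaluator:
    """Solves rates and accumulates row log-likelihood terms, de-duplicating
    repeated ``(mu, nu)`` pairs (factorial designs repeat heavily)."""

    def __init__(self, data: RegressionData, config: MCMCConfig, table=None):
        self.data = data
        self.method = config.solver
        self.table = table
        self.tol = config.tol
        if config.solver == "lookup" and table is None:
            raise ConfigurationError("solver='lookup' requires a look-up table")
        if data.support_bound is not None:
            self.k = int(data.support_bound)
            self.mode = BOUND
        elif config.k is not None:
            self.k = int(config.k)
            self.mode = SERIES
        elif table is not None:
            self.k = int(table.trunc_k)
            self.mode = SERIES
        else:
            self.k = max(60, 6 * int(data.y.max(initial=1)))
            self.mode = SERIES
        self.log_fact_y = gammaln(data.y + 1.0)

    def log_lambda_log_G(self, mu: np.ndarray, nu: np.ndarray, method=None):
        """Vectorised ``(log lambda_i, log G_i)``; raises ConvergenceError
        when any pair is unsolvable under the truncation."""
        method = method or self.method
        pairs = np.column_stack([mu, nu])
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        umu, unu = uniq[:, 0], uniq[:, 1]
        if method == "lookup":
            log_lam_u = np.atleast_1d(self.table.query(umu, unu))
            log_G_u, _, _ = moments(log_lam_u, unu, self.k)
        elif method == "bisection":
            if np.any(umu >= self.k):
                bad = np.flatnonzero(umu >= self.k)[0]
                raise ConvergenceError(
                    "mean not attainable under truncation",
                    mu=float(umu[bad]),
                    nu=float(unu[bad]),
                )
            log_lam_u, log_G_u = solve_log_lambda_many(umu, unu, k=self.k, tol=self.tol)
        elif method == "polynomial":
            rates = [solve_lambda_polynomial(m, n, k=self.k) for m, n in zip(umu, unu)]
            log_lam_u = np.array([r.log_lambda for r in rates])
            log_G_u = np.array([r.log_G for r in rates])
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown solver {method!r}")
        return log_lam_u[inv], log_G_u[inv]

    def row_loglik(self, mu: np.ndarray, nu: np.ndarray, method=None):
        """Per-row ``y log lambda - nu log(y!) - log G``; None when the
        rate solve fails (treated by callers as a -inf posterior)."""
        try:
            log_lam, log_G = self.log_lambda_log_G(mu, nu, method=method)
        except ConvergenceError as exc:
            logger.warning("rate solve failed (mu=%s, nu=%s); rejecting proposal", exc.mu, exc.nu)
            return None
        return self.data.y * log_lam - nu * self.log_fact_y - log_G


def _mvn_logpdf_quad(x, mean, cov_inv):
    d = x - mean
    return -0.5 * float(d @ cov_inv @ d)


def log_cond_posterior_beta(beta, gamma, data: RegressionData, prior: PriorSpec,
                            solver: str = "bisection", table=None, theta=None,
                            config: MCMCConfig | None = None) -> float:
    """Conditional log-posterior of the mean coefficients (up to a constant).

    ``log pi(beta) + sum_i [y_i log lambda_i - log G_i]``; the
    ``nu log(y!)`` term is constant in ``beta`` and omitted.
    """
    config = config or MCMCConfig(iterations=1, warmup=0, solver=solver)
    prior = prior.validated(data)
    ev = _Evaluator(data, config, table=table)
    mu = fitted_mean(data, beta, theta)
    nu = np.exp(data.X2 @ np.asarray(gamma, dtype=float))
    log_lam, log_G = ev.log_lambda_log_G(mu, nu)
    lp = float(np.sum(data.y * log_lam - log_G))
    return lp + _mvn_logpdf_quad(np.asarray(beta, float), prior.beta_mean,
                                 np.linalg.inv(prior.beta_cov))


def log_cond_posterior_gamma(gamma, beta, data: RegressionData, prior: PriorSpec,
                             solver: str = "bisection", table=None, theta=None,
                             config: MCMCConfig | None = None) -> float:
    """Conditional log-posterior of the dispersion coefficients.

    As the beta conditional plus the data-dependent ``- sum_i nu_i log(y_i!)``
    term through which the dispersion acts on the factorial weights.
    """
    config = config or MCMCConfig(iterations=1, warmup=0, solver=solver)
    prior = prior.validated(data)
    ev = _Evaluator(data, config, table=table)
    mu = fitted_mean(data, beta, theta)
    gamma = np.asarray(gamma, dtype=float)
    nu = np.exp(data.X2 @ gamma)
    ll = ev.row_loglik(mu, nu)
    if ll is None:
        return -np.inf
    lp = float(np.sum(ll))
    return lp + float(np.sum(-0.5 * (gamma - prior.gamma_mean) ** 2 / prior.gamma_var))


# -- the Metropolis-within-Gibbs driver ------------------------------------


def _poisson_glm_start(data: RegressionData):
    """Starting beta and proposal covariance from a Poisson GLM fit."""
    import statsmodels.api as sm

    try:
        fit = sm.GLM(
            data.y, data.X1, family=sm.families.Poisson(), offset=data.offset
        ).fit()
        cov = np.asarray(fit.cov_params())
        # guard against near-singular covariances from quasi-separated fits
        if not np.all(np.isfinite(cov)) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("non-PD GLM covariance")
        return np.asarray(fit.params), cov
    except Exception:  # fall back to a flat start
        logger.warning("Poisson GLM start failed; using zero start")
        beta = np.zeros(data.p)
        if np.all(data.X1[:, 0] == 1.0):
            beta[0] = math.log(data.y.mean() + 0.1)
        return beta, 0.01 * np.eye(data.p)


def _is_partition(X2: np.ndarray) -> bool:
    """True when the dispersion design is an indicator partition of the rows
    (each row has exactly one unit entry), enabling independent parallel
    scalar updates of the gamma components."""
    if not np.all((X2 == 0.0) | (X2 == 1.0)):
        return False
    return bool(np.all(X2.sum(axis=1) == 1.0))


def run_mwg(
    data: RegressionData,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    table=None,
) -> ChainResult:
    """Run one Metropolis-within-Gibbs chain and return its draws.

    Reproducible given ``config.seed``; the per-iteration RNG consumption is
    fixed, so chains with identical seeds but different rate solvers see
    identical proposal noise and differ only through the lambda evaluation.
    """
    config = config or MCMCConfig()
    prior = (prior or PriorSpec()).validated(data)
    ev = _Evaluator(data, config, table=table)
    if table is not None:
        table.reset_extrapolation_log()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    p, q, m = data.p, data.q, data.m
    use_theta = m > 0
    partition = _is_partition(data.X2)
    if partition:
        comp_of_row = np.argmax(data.X2, axis=1)

    beta, glm_cov = _poisson_glm_start(data)
    gamma = np.zeros(q)
    theta = np.zeros(m) if use_theta else None
    n_free = (m - 1) if (use_theta and config.sum_to_zero) else m

    prop_cov = config.beta_proposal_cov if config.beta_proposal_cov is not None else glm_cov
    L_beta = np.linalg.cholesky(prop_cov)
    s_beta = 2.38 / math.sqrt(p)
    s_theta = config.theta_proposal_scale
    s_gamma = np.full(q, config.gamma_proposal_scale)

    beta_cov_inv = np.linalg.inv(prior.beta_cov)
    theta_cov_inv = np.linalg.inv(prior.theta_cov) if use_theta else None

    def theta_from_free(phi):
        if not use_theta:
            return None
        if config.sum_to_zero:
            return np.append(phi, -phi.sum())
        return phi

    phi = np.zeros(n_free) if use_theta else None

    def lprior_beta(b):
        return _mvn_logpdf_quad(b, prior.beta_mean, beta_cov_inv)

    def lprior_theta(t):
        return _mvn_logpdf_quad(t, prior.theta_mean, theta_cov_inv)

    def lprior_gamma_comp(g):
        return -0.5 * (g - prior.gamma_mean) ** 2 / prior.gamma_var

    # current state caches
    nu = np.exp(data.X2 @ gamma)
    mu = fitted_mean(data, beta, theta)
    row_ll = ev.row_loglik(mu, nu)
    if row_ll is None or not np.all(np.isfinite(row_ll)):
        raise SamplerError(
            f"initial state unevaluable: beta={beta}, gamma={gamma}, theta={theta}"
        )

    n_keep = config.iterations // config.thin
    out_beta = np.empty((n_keep, p))
    out_gamma = np.empty((n_keep, q))
    out_theta = np.empty((n_keep, m)) if use_theta else None
    warm_times = np.empty(config.warmup)
    main_times = np.empty(config.iterations)
    acc_counts = {"beta": 0, "theta": 0, "gamma": 0}
    n_main = 0
    target_beta = 0.234 if p > 1 else 0.44
    target_theta = 0.234 if n_free > 1 else 0.44

    def _check(lp, label, state):
        if np.isnan(lp):
            raise SamplerError(f"NaN in {label} conditional; state dump: {state!r}")

    keep_idx = 0
    total = config.warmup + config.iterations
    for it in range(total):
        t0 = time.perf_counter()
        warm = it < config.warmup
        gain = 1.0 / (it + 1) ** 0.6

        # ---- beta block -------------------------------------------------
        z = rng.standard_normal(p)
        u = rng.random()
        beta_prop = beta + s_beta * (L_beta @ z)
        mu_prop = fitted_mean(data, beta_prop, theta)
        ll_prop = ev.row_loglik(mu_prop, nu)
        if ll_prop is None:
            alpha = 0.0
        else:
            lp_diff = (ll_prop.sum() + lprior_beta(beta_prop)) - (
                row_ll.sum() + lprior_beta(beta)
            )
            _check(lp_diff, "beta", {"beta": beta_prop, "gamma": gamma, "theta": theta})
            alpha = min(1.0, math.exp(min(lp_diff, 0.0)))
        if u < alpha:
            beta, mu, row_ll = beta_prop, mu_prop, ll_prop
            if not warm:
                acc_counts["beta"] += 1
        if warm and config.adapt:
            s_beta *= math.exp(gain * (alpha - target_beta))

        # ---- theta block ------------------------------------------------
        if use_theta:
            z = rng.standard_normal(n_free)
            u = rng.random()
            phi_prop = phi + s_theta * z
            theta_prop = theta_from_free(phi_prop)
            mu_prop = fitted_mean(data, beta, theta_prop)
            ll_prop = ev.row_loglik(mu_prop, nu)
            if ll_prop is None:
                alpha = 0.0
            else:
                lp_diff = (ll_prop.sum() + lprior_theta(theta_prop)) - (
                    row_ll.sum() + lprior_theta(theta)
                )
                _check(lp_diff, "theta", {"beta": beta, "gamma": gamma, "theta": theta_prop})
                alpha = min(1.0, math.exp(min(lp_diff, 0.0)))
            if u < alpha:
                phi, theta, mu, row_ll = phi_prop, theta_prop, mu_prop, ll_prop
                if not warm:
                    acc_counts["theta"] += 1
            if warm and config.adapt:
                s_theta *= math.exp(gain * (alpha - target_theta))

        # ---- gamma components (log-dispersion scale) --------------------
        z = rng.standard_normal(q)
        u = rng.random(q)
        if not config.fix_gamma:
            gamma_prop = gamma + s_gamma * z
            if partition:
                # components act on disjoint row sets: independent updates
                nu_prop = np.exp(data.X2 @ gamma_prop)
                ll_prop = ev.row_loglik(mu, nu_prop)
                if ll_prop is None:
                    alpha_vec = np.zeros(q)
                else:
                    delta_rows = ll_prop - row_ll
                    delta = np.bincount(comp_of_row, weights=delta_rows, minlength=q)
                    delta += lprior_gamma_comp(gamma_prop) - lprior_gamma_comp(gamma)
                    _check(delta.sum(), "gamma", {"beta": beta, "gamma": gamma_prop})
                    alpha_vec = np.minimum(1.0, np.exp(np.minimum(delta, 0.0)))
                acc = u < alpha_vec
                if acc.any() and ll_prop is not None:
                    gamma = np.where(acc, gamma_prop, gamma)
                    rows_acc = acc[comp_of_row]
                    row_ll = np.where(rows_acc, ll_prop, row_ll)
                    nu = np.exp(data.X2 @ gamma)
                if not warm:
                    acc_counts["gamma"] += int(acc.sum())
                if warm and config.adapt:
                    s_gamma *= np.exp(gain * (alpha_vec - 0.44))
            else:
                for j in range(q):
                    gamma_prop = gamma.copy()
                    gamma_prop[j] += s_gamma[j] * z[j]
                    nu_prop = np.exp(data.X2 @ gamma_prop)
                    ll_prop = ev.row_loglik(mu, nu_prop)
                    if ll_prop is None:
                        alpha = 0.0
                    else:
                        lp_diff = float(
                            ll_prop.sum()
                            - row_ll.sum()
                            + lprior_gamma_comp(gamma_prop)[j]
                            - lprior_gamma_comp(gamma)[j]
                        )
                        _check(lp_diff, "gamma", {"beta": beta, "gamma": gamma_prop})
                        alpha = min(1.0, math.exp(min(lp_diff, 0.0)))
                    if u[j] < alpha:
                        gamma, nu, row_ll = gamma_prop, nu_prop, ll_prop
                        if not warm:
                            acc_counts["gamma"] += 1
                    if warm and config.adapt:
                        s_gamma[j] *= math.exp(gain * (alpha - 0.44))

        dt = time.perf_counter() - t0
        if warm:
            warm_times[it] = dt
        else:
            main_times[it - config.warmup] = dt
            n_main += 1
            j = it - config.warmup
            if (j + 1) % config.thin == 0:
                out_beta[keep_idx] = beta
                out_gamma[keep_idx] = gamma
                if use_theta:
                    out_theta[keep_idx] = theta
                keep_idx += 1

    names = list(data.x1_names) + list(data.x2_names)
    if use_theta:
        names += [f"theta[{i}]" for i in range(m)]
    denom = max(n_main, 1)
    accept_rates = {
        "beta": acc_counts["beta"] / denom,
        "theta": acc_counts["theta"] / denom if use_theta else np.nan,
        "gamma": acc_counts["gamma"] / (denom * q) if not config.fix_gamma else np.nan,
    }
    return ChainResult(
        beta=out_beta[:keep_idx],
        gamma=out_gamma[:keep_idx],
        theta=out_theta[:keep_idx] if use_theta else None,
        accept_rates=accept_rates,
        iter_times=main_times,
        warmup_times=warm_times,
        config=config,
        param_names=names,
        table=table,
        proposal_scales={"beta": s_beta, "theta": s_theta, "gamma": s_gamma.copy()},
    )


def run_chains(
    data: RegressionData,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    table=None,
    chains: int = 4,
    n_jobs: int = 1,
) -> list:
    """Run several independent chains (seeds spawned from ``config.seed``)."""
    config = config or MCMCConfig()
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(chains)]
    configs = []
    for s in seeds:
        c = MCMCConfig(**{**config.__dict__, "seed": s})
        configs.append(c)
    if n_jobs > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=n_jobs)(
            delayed(run_mwg)(data, prior, c, table) for c in configs
        )
    return [run_mwg(data, prior, c, table) for c in configs]


# -- summaries and convergence plumbing ------------------------------------


def highest_density_interval(draws: np.ndarray, level: float = 0.95):
    """Shortest interval containing ``level`` mass of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    K = len(x)
    w = int(math.ceil(level * K))
    if w >= K:
        return float(x[0]), float(x[-1])
    widths = x[w - 1:] - x[: K - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation ESS (Geyer initial positive sequence), one chain."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs until a pair goes non-positive
    s = 0.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def split_rhat(chains_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor; input (chains, draws)."""
    x = np.asarray(chains_draws, dtype=float)
    half = x.shape[1] // 2
    if half < 2:
        return float("nan")
    splits = np.vstack([x[:, :half], x[:, half: 2 * half]])
    mchain, ndraw = splits.shape
    means = splits.mean(axis=1)
    B = ndraw * means.var(ddof=1)
    W = splits.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (ndraw - 1) / ndraw * W + B / ndraw
    return float(math.sqrt(var_plus / W))


def posterior_summary(chain, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, SD, HDI, ESS and (multi-chain) split R-hat.

    ``chain`` may be a single :class:`ChainResult` or a list of them.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    chains = chain if isinstance(chain, (list, tuple)) else [chain]
    names = chains[0].param_names
    mats = [c.draws_matrix() for c in chains]
    pooled = np.vstack(mats)
    if pooled.shape[0] < 100:
        logger.warning("posterior_summary called with fewer than 100 draws")
    rows = []
    for j, name in enumerate(names):
        draws = pooled[:, j]
        lo, hi = highest_density_interval(draws, level)
        ess = sum(effective_sample_size(mat[:, j]) for mat in mats)
        rhat = (
            split_rhat(np.vstack([mat[:, j] for mat in mats]))
            if len(mats) > 1
            else split_rhat(draws[None, :])
        )
        sd = draws.std(ddof=1)
        rows.append(
            {
                "parameter": name,
                "mean": draws.mean(),
                "sd": sd,
                f"hdi_{level:.0%}_lower": lo,
                f"hdi_{level:.0%}_upper": hi,
                "ess": ess,
                "mcse": sd / math.sqrt(max(ess, 1.0)),
                "rhat": rhat,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
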