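"""Importance-ratio diagnostics for the look-up approximation, plus timing.

A chain run with the interpolated look-up table targets an *approximate*
posterior ``pi~`` in which every ``lambda_i`` is the interpolated value.
For each retained draw the ratio

    r(beta, gamma) = pi(beta, gamma | y) / pi~(beta, gamma | y)

against the exact posterior (rates re-solved by bisection or polynomial
root extraction; priors and factorial terms cancel) measures how far the
approximation bends the target, and the approximate effective sample size

    m_e = (sum_k r_k)^2 / sum_k r_k^2,   1 <= m_e <= K,

says how many of the K draws survive reweighting onto the exact posterior:
m_e = K iff the ratios are constant, i.e. the table changes nothing but an
overall normalisation.  This is *not* the autocorrelation ESS of the chain;
it isolates the information lost to interpolation alone.

Ratios are handled in log space throughout; because m_e is invariant to
rescaling all ratios by a positive constant, subtracting the maximum log
ratio before exponentiating is exact, not an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    InvalidArgumentError,
    RootSelectionError,
)
from .lambda_solver import solve_lambda_polynomial
from .sampler import ChainResult, RegressionData, _Evaluator, fitted_mean

__all__ = [
    "ImportanceDiagnostic",
    "importance_log_ratios",
    "importance_ratios",
    "approx_ess",
    "importance_diagnostic",
    "timing_report",
    "TimingReport",
]

logger = logging.getLogger(__name__)

DEFAULT_K_DRAWS = 1000


@dataclass
class ImportanceDiagnostic:
    """Ratios and m_e for one chain/reference pairing."""

    log_ratios: np.ndarray
    m_e: float
    reference_method: str
    K: int

    @property
    def ratios(self) -> np.ndarray:
        return np.exp(self.log_ratios - self.log_ratios.max())


def _chain_states(chain: ChainResult, K: int):
    """The last K retained draws as (beta, gamma, theta) triples."""
    n = chain.n_draws
    K = min(K, n)
    sl = slice(n - K, n)
    thetas = chain.theta[sl] if chain.theta is not None else [None] * K
    return chain.beta[sl], chain.gamma[sl], thetas, K


def importance_log_ratios(
    chain: ChainResult,
    data: RegressionData,
    reference: str = "bisection",
    K: int = DEFAULT_K_DRAWS,
) -> np.ndarray:
    """Per-draw log ratio of the exact over the look-up posterior.

    The chain must have been run with the look-up solver (its table is
    reused for the approximate side).  Priors are identical on both sides
    and cancel, so only ``sum_i [y_i d(log lambda_i) - d(log G_i)]``
    survives.  Draws where the reference solver fails are dropped with a
    warning and K reduced.
    """
    if reference not in ("bisection", "polynomial", "lookup"):
        raise ConfigurationError(f"unknown reference solver {reference!r}")
    if chain.config.solver != "lookup" or chain.table is None:
        raise ConfigurationError(
            "importance ratios quantify the look-up approximation; "
            "the chain must have been run with solver='lookup'"
        )
    ev = _Evaluator(data, chain.config, table=chain.table)
    betas, gammas, thetas, K = _chain_states(chain, K)
    y = np.asarray(data.y, dtype=float)

    # de-duplicate (mu, nu) within each draw, then batch the rate solves
    # across draws so the vectorised solver sees large arrays
    per_draw = []
    for beta, gamma, theta in zip(betas, gammas, thetas):
        mu = fitted_mean(data, beta, theta)
        nu = np.exp(data.X2 @ gamma)
        uniq, inv = np.unique(np.column_stack([mu, nu]), axis=0, return_inverse=True)
        per_draw.append((uniq, inv))
    max_u = max(u.shape[0] for u, _ in per_draw)
    block = max(1, 200_000 // max_u)  # cap solver working-set size

    out = []
    from .core_dist import moments as _moments
    from .lambda_solver import solve_log_lambda_many as _solve

    for start in range(0, K, block):
        chunk = per_draw[start: start + block]
        uniq_all = np.vstack([u for u, _ in chunk])
        umu, unu = uniq_all[:, 0], uniq_all[:, 1]
        log_lam_a = np.atleast_1d(chain.table.query(umu, unu))
        log_G_a, _, _ = _moments(log_lam_a, unu, ev.k)
        solvable = umu < ev.k  # mean unattainable under the truncation otherwise
        log_lam_e = np.full(len(uniq_all), np.nan)
        log_G_e = np.full(len(uniq_all), np.nan)
        if reference == "lookup":
            log_lam_e, log_G_e = log_lam_a, log_G_a
        elif reference == "bisection":
            if solvable.any():
                ll, lg = _solve(umu[solvable], unu[solvable], k=ev.k, tol=ev.tol)
                log_lam_e[solvable], log_G_e[solvable] = ll, lg
        else:  # polynomial
            for i in np.flatnonzero(solvable):
                try:
                    rp = solve_lambda_polynomial(umu[i], unu[i], k=ev.k)
                except (ConvergenceError, RootSelectionError, InvalidArgumentError):
                    solvable[i] = False
                    continue
                log_lam_e[i], log_G_e[i] = rp.log_lambda, rp.log_G
        d_lam = log_lam_e - log_lam_a
        d_G = log_G_e - log_G_a
        pos = 0
        for uniq, inv in chunk:
            u = uniq.shape[0]
            seg = slice(pos, pos + u)
            if not solvable[seg].all():
                bad = np.flatnonzero(~solvable[seg])[0]
                logger.warning(
                    "reference solver failed at a draw (mu=%.4g, nu=%.4g); dropping it",
                    uniq[bad, 0],
                    uniq[bad, 1],
                )
                pos += u
                continue
            out.append(float(np.sum(y * d_lam[seg][inv] - d_G[seg][inv])))
            pos += u
    return np.asarray(out)


def importance_ratios(
    chain: ChainResult,
    data: RegressionData,
    prior=None,
    reference: str = "bisection",
    K: int = DEFAULT_K_DRAWS,
) -> np.ndarray:
    """Importance ratios stabilised by the maximum log ratio.

    ``prior`` is accepted for interface symmetry but unused: identical
    priors appear in numerator and denominator of the ratio and cancel.
    """
    lr = importance_log_ratios(chain, data, reference=reference, K=K)
    return np.exp(lr - lr.max())


def approx_ess(ratios) -> float:
    """``m_e = (sum r)^2 / sum r^2``; invariant to rescaling the ratios."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise InvalidArgumentError("ratios must be non-empty")
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise InvalidArgumentError("ratios must be finite and positive")
    return float(r.sum() ** 2 / np.sum(r * r))


def approx_ess_from_log(log_ratios) -> float:
    """m_e straight from log ratios (max-stabilised internally)."""
    lr = np.asarray(log_ratios, dtype=float)
    if lr.size == 0:
        raise InvalidArgumentError("log ratios must be non-empty")
    if np.any(~np.isfinite(lr)):
        raise InvalidArgumentError("log ratios must be finite")
    return approx_ess(np.exp(lr - lr.max()))


def importance_diagnostic(
    chain: ChainResult,
    data: RegressionData,
    reference: str = "bisection",
    K: int = DEFAULT_K_DRAWS,
) -> ImportanceDiagnostic:
    """Convenience wrapper returning ratios and m_e together."""
    lr = importance_log_ratios(chain, data, reference=reference, K=K)
    return ImportanceDiagnostic(
        log_ratios=lr,
        m_e=approx_ess_from_log(lr),
        reference_method=reference,
        K=len(lr),
    )


# -- timing ---------------------------------------------------------------


@dataclass
class TimingReport:
    """Per-method iteration-time summaries and cumulative-time crossovers."""

    summary: pd.DataFrame
    cumulative: dict
    crossover: dict


def timing_report(chains) -> TimingReport:
    """Compare per-iteration times across chains run with different solvers.

    The cumulative curve of a look-up chain includes its table build time
    (front-loaded cost); the crossover entry for (lookup, other) is the
    first iteration at which the look-up total, build included, undercuts
    the other method's total, or None if it never does within the run.
    """
    chains = chains if isinstance(chains, (list, tuple)) else [chains]
    rows = []
    cumulative = {}
    for c in chains:
        method = c.config.solver
        t = np.asarray(c.iter_times, dtype=float)
        start = c.table_build_time if method == "lookup" else 0.0
        cumulative[method] = start + np.cumsum(t)
        rows.append(
            {
                "method": method,
                "iterations": len(t),
                "mean_iter_time": t.mean(),
                "sd_iter_time": t.std(ddof=1) if len(t) > 1 else 0.0,
                "total_time": start + t.sum(),
                "table_build_time": start,
            }
        )
    summary = pd.DataFrame(rows).set_index("method")
    crossover = {}
    if "lookup" in cumulative:
        cl = cumulative["lookup"]
        for method, cm in cumulative.items():
            if method == "lookup":
                continue
            n = min(len(cl), len(cm))
            ahead = np.flatnonzero(cl[:n] <= cm[:n])
            crossover[method] = int(ahead[0]) + 1 if ahead.size else None
    return TimingReport(summary=summary, cumulative=cumulative, crossover=crossover)
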