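"""Exact solvers for the rate ``lambda(mu, nu)`` of the MPCMP distribution.

The mean of the CMP distribution is strictly increasing in ``log lambda``
(its derivative is the variance), so the mean constraint ``E[Y] = mu`` has a
unique root.  Two exact routes are provided:

* a safeguarded Newton iteration on ``log lambda`` inside a sign-changing
  bracket (Newton steps that leave the bracket fall back to bisection) --
  the work-horse, fully vectorised over arrays of ``(mu, nu)`` pairs;
* direct root extraction from the degree-``k`` polynomial
  ``sum_r (r - mu) lambda^r / (r!)^nu = 0``.  Because the coefficients are
  negative for ``r < mu`` and positive for ``r > mu`` there is a single sign
  change and hence, by Descartes' rule of signs, a solitary positive real
  root, which companion-matrix eigenvalues recover without iteration.

``solve_lambda`` dispatches between these and the interpolated look-up
table; the normalising constant in the returned :class:`RatePair` is always
recomputed from the returned ``log lambda`` so downstream pmf arithmetic is
self-consistent whichever route produced the rate.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.special import gammaln

from .core_dist import (
    DEFAULT_K,
    SERIES,
    RatePair,
    TruncationSpec,
    default_truncation,
    log_normalising_constant,
    moments,
)
from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    InvalidArgumentError,
    RootSelectionError,
)

__all__ = [
    "solve_lambda_bisection",
    "solve_lambda_polynomial",
    "solve_lambda",
    "solve_log_lambda_many",
]

logger = logging.getLogger(__name__)

#: tolerance on log lambda for the bracketed solver
DEFAULT_TOL = 1e-10

_MAX_BRACKET_DOUBLINGS = 200
_MAX_NEWTON_ITER = 200


def _initial_log_lambda(mu: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Starting point from the classical approximation lambda ~ (mu + (nu-1)/(2 nu))^nu.

    Exact at nu = 1; at nu = 0 the geometric value mu/(1+mu) is used.  The
    argument is floored at mu/2 to stay positive for small nu.
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    out = np.empty(np.broadcast(mu, nu).shape)
    mu_b, nu_b = np.broadcast_arrays(mu, nu)
    pos = nu_b > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = mu_b + (nu_b - 1.0) / np.where(pos, 2.0 * nu_b, 1.0)
    arg = np.maximum(arg, np.maximum(mu_b / 2.0, 1e-12))
    out[pos] = nu_b[pos] * np.log(arg[pos])
    out[~pos] = np.log(mu_b[~pos] / (1.0 + mu_b[~pos]))
    return out


def solve_log_lambda_many(mu, nu, k: int = DEFAULT_K, tol: float = DEFAULT_TOL):
    """Vectorised safeguarded-Newton solve of the mean constraint.

    Returns ``(log_lambda, log_G)`` arrays with
    ``|mean(log_lambda, nu) - mu| / mu < 10 * tol`` elementwise.

    Raises :class:`ConvergenceError` (reporting the offending ``(mu, nu)``)
    if a sign-changing bracket cannot be established, which happens exactly
    when ``mu`` is not attainable under the truncation (``mu`` at or above
    the largest mean the k-term distribution can reach).
    """
    if not tol > 0:
        raise InvalidArgumentError("tol must be positive")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    mu, nu = np.broadcast_arrays(mu, nu)
    mu = mu.copy()
    nu = nu.copy()
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        raise InvalidArgumentError("mu must be positive and finite")
    if np.any(~np.isfinite(nu)) or np.any(nu < 0):
        raise InvalidArgumentError("nu must be non-negative and finite")
    if np.any(mu >= k):
        bad = np.flatnonzero(mu >= k)[0]
        raise ConvergenceError(
            f"mu={mu[bad]:.6g} is not attainable with k={k} series terms",
            mu=float(mu[bad]),
            nu=float(nu[bad]),
        )

    t = _initial_log_lambda(mu, nu)
    _, mean, _ = moments(t, nu, k)
    f = mean - mu

    # establish lo with f(lo) < 0 and hi with f(hi) > 0 by geometric expansion
    lo = np.where(f < 0, t, np.nan)
    hi = np.where(f >= 0, t, np.nan)
    step = math.log(2.0)
    for i in range(_MAX_BRACKET_DOUBLINGS):
        need_lo = np.isnan(lo)
        need_hi = np.isnan(hi)
        if not (need_lo.any() or need_hi.any()):
            break
        if need_lo.any():
            idx = np.flatnonzero(need_lo)
            cand = hi[idx] - step * (2.0**i)
            _, m_lo, _ = moments(cand, nu[idx], k)
            ok = m_lo - mu[idx] < 0
            lo[idx[ok]] = cand[ok]
        if need_hi.any():
            idx = np.flatnonzero(need_hi)
            cand = lo[idx] + step * (2.0**i)
            _, m_hi, _ = moments(cand, nu[idx], k)
            ok = m_hi - mu[idx] >= 0
            hi[idx[ok]] = cand[ok]
    else:
        bad = np.flatnonzero(np.isnan(lo) | np.isnan(hi))[0]
        raise ConvergenceError(
            "bracket expansion failed for the mean constraint",
            mu=float(mu[bad]),
            nu=float(nu[bad]),
        )

    t = 0.5 * (lo + hi)
    out = np.empty_like(t)
    active = np.arange(t.size)
    for _ in range(_MAX_NEWTON_ITER):
        ta, nua, mua = t[active], nu[active], mu[active]
        _, mean, var = moments(ta, nua, k)
        f = mean - mua
        neg = f < 0
        lo[active[neg]] = ta[neg]
        hi[active[~neg]] = ta[~neg]
        done = (np.abs(f) <= 10.0 * tol * mua) | (hi[active] - lo[active] <= tol)
        if done.any():
            out[active[done]] = ta[done]
            active = active[~done]
            if active.size == 0:
                break
            f, var = f[~done], var[~done]
            ta = ta[~done]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_new = ta - f / var
        mid = 0.5 * (lo[active] + hi[active])
        bad = ~np.isfinite(t_new) | (t_new <= lo[active]) | (t_new >= hi[active])
        t_new[bad] = mid[bad]
        t[active] = t_new
    else:  # pragma: no cover - Newton + bisection cannot stall within the budget
        bad = active[0]
        raise ConvergenceError(
            "mean-constraint solve did not converge",
            mu=float(mu[bad]),
            nu=float(nu[bad]),
        )

    lw_logG, _, _ = moments(out, nu, k)
    return out, lw_logG


def solve_lambda_bisection(
    mu: float,
    nu: float,
    trunc: TruncationSpec | None = None,
    tol: float = DEFAULT_TOL,
) -> RatePair:
    """Solve the mean constraint for a single ``(mu, nu)`` pair.

    ``trunc`` defaults to series truncation at ``max(60, ceil(2 mu))``
    terms.  In series mode with ``nu = 0`` the solution is only meaningful
    when the implied geometric series converges (``lambda < 1``); otherwise
    a :class:`ConvergenceError` is raised rather than silently truncating a
    divergent series.
    """
    trunc = trunc if trunc is not None else default_truncation(mu)
    log_lam, log_G = solve_log_lambda_many(mu, nu, k=trunc.k, tol=tol)
    log_lam, log_G = float(log_lam[0]), float(log_G[0])
    if nu == 0 and trunc.mode == SERIES and log_lam >= 0.0:
        raise ConvergenceError(
            "nu = 0 with lambda >= 1: the geometric series diverges; "
            "declare a hard support bound instead",
            mu=mu,
            nu=nu,
        )
    return RatePair(log_lam, log_G)


def _positive_real_roots(roots: np.ndarray) -> np.ndarray:
    real = roots.real
    keep = (np.abs(roots.imag) < 1e-8 * (1.0 + np.abs(real))) & (real > 0)
    return real[keep]


def solve_lambda_polynomial(mu: float, nu: float, k: int = DEFAULT_K) -> RatePair:
    """Extract ``lambda`` as the unique positive real root of the rate polynomial.

    The coefficients ``c_r = (r - mu) / (r!)^nu`` are assembled in log space
    with explicit signs, rescaled in the variable ``x = lambda / s`` (with
    ``s`` the Newton starting approximation) and normalised by the largest
    magnitude before companion-matrix root extraction, which keeps the root
    of interest near one and the conditioning benign even for large ``k``
    or ``nu``.
    """
    if not (np.isfinite(mu) and mu > 0):
        raise InvalidArgumentError("mu must be positive and finite")
    if not (np.isfinite(nu) and nu >= 0):
        raise InvalidArgumentError("nu must be non-negative and finite")
    if k < math.ceil(mu) + 1:
        raise InvalidArgumentError(
            f"k={k} too small for mu={mu}: need k >= ceil(mu)+1 for the single sign change"
        )
    r = np.arange(k + 1, dtype=float)
    diff = r - mu
    log_s = float(_initial_log_lambda(np.array([mu]), np.array([nu]))[0])
    with np.errstate(divide="ignore"):
        log_c = np.log(np.abs(diff)) - nu * gammaln(r + 1.0) + r * log_s
    finite = np.isfinite(log_c)
    scale = log_c[finite].max()
    # Trim trailing terms that cannot move the scaled root: with x = lambda/s
    # near one, a term of relative size |c_r| x^r < 1e-40 (taking |x| <= 4)
    # is far below double precision.  This keeps the leading coefficient
    # representable so the companion matrix stays finite.
    contrib = np.where(finite, log_c - scale, -np.inf) + r * math.log(4.0)
    r_max = max(int(np.flatnonzero(contrib > -40 * math.log(10.0)).max()), math.ceil(mu) + 1)
    coeffs = np.where(finite[: r_max + 1], np.sign(diff[: r_max + 1]) *
                      np.exp(log_c[: r_max + 1] - scale), 0.0)
    roots = np.roots(coeffs[::-1])  # highest degree first
    candidates = _positive_real_roots(roots)
    if candidates.size == 0:
        raise RootSelectionError(
            f"no positive real root for (mu={mu}, nu={nu}, k={k}); k may be too small"
        )
    log_lams = np.log(candidates) + log_s
    if candidates.size > 1:
        _, means, _ = moments(log_lams, np.full(candidates.size, nu), k)
        resid = np.abs(means - mu)
        order = np.argsort(resid)
        if resid[order[1]] < 1e-6 * (1.0 + mu):  # genuinely ambiguous
            raise RootSelectionError(
                f"multiple admissible positive roots for (mu={mu}, nu={nu}, k={k})"
            )
        logger.warning(
            "polynomial solver found %d positive real roots for (mu=%g, nu=%g); "
            "keeping the one matching the mean constraint",
            candidates.size,
            mu,
            nu,
        )
        log_lam = float(log_lams[order[0]])
    else:
        log_lam = float(log_lams[0])
    log_G = log_normalising_constant(log_lam, nu, TruncationSpec.series(k))
    return RatePair(log_lam, float(log_G))


def solve_lambda(
    mu: float,
    nu: float,
    method: str = "bisection",
    *,
    trunc: TruncationSpec | None = None,
    table=None,
    tol: float = DEFAULT_TOL,
) -> RatePair:
    """Uniform dispatch over the three rate-solving routes.

    ``method`` is one of ``bisection``, ``polynomial`` or ``lookup`` (the
    latter requires ``table``); ``log_G`` is always recomputed from the
    returned ``log lambda``.
    """
    trunc = trunc if trunc is not None else default_truncation(mu)
    if method == "bisection":
        return solve_lambda_bisection(mu, nu, trunc=trunc, tol=tol)
    if method == "polynomial":
        return solve_lambda_polynomial(mu, nu, k=trunc.k)
    if method == "lookup":
        if table is None:
            raise ConfigurationError("method='lookup' requires a LookupTable in context")
        log_lam = float(table.query(mu, nu))
        log_G = log_normalising_constant(log_lam, nu, trunc)
        return RatePair(log_lam, float(log_G))
    raise ConfigurationError(f"unknown solver method {method!r}")
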