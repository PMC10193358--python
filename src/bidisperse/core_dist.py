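"""The mean-parameterised Conway-Maxwell-Poisson (MPCMP) distribution.

The CMP pmf with rate ``lambda > 0`` and dispersion ``nu >= 0`` is

    Pr(Y = y | lambda, nu) = lambda^y / (y!)^nu / G(lambda, nu),
    G(lambda, nu) = sum_r lambda^r / (r!)^nu,

which is Poisson at ``nu = 1``, geometric at ``nu = 0`` (for ``lambda < 1``)
and increasingly underdispersed as ``nu`` grows.  The mean-parameterised
family replaces ``lambda`` by the solution ``lambda(mu, nu)`` of the mean
constraint ``E[Y] = mu``, so that regression models can act on the mean
directly.  This module provides the truncated-series building blocks:
normalising constant, pmf, moments and variate generation, all in log space
via log-sum-exp so that no intermediate quantity overflows.

The infinite series is always evaluated as a finite sum over ``r = 0..k``.
Two truncation policies exist: ``series-truncation`` (``k`` chosen large
enough, about twice the largest mean of interest, that the discarded tail is
negligible) and ``hard-support-bound`` (the support really is ``{0..k}``,
e.g. at most ten wickets can fall in a cricket innings, so the sum is finite
by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import InvalidArgumentError

__all__ = [
    "TruncationSpec",
    "MPCMPSpec",
    "RatePair",
    "default_truncation",
    "log_normalising_constant",
    "mpcmp_mean",
    "mpcmp_log_pmf",
    "mpcmp_pmf_vector",
    "mpcmp_variance",
    "rmpcmp",
    "rmpcmp_rowwise",
    "log_weights",
    "moments",
]

#: default number of series terms; about twice the largest mean the default
#: look-up grid covers (mu_max = 32).
DEFAULT_K = 60

SERIES = "series-truncation"
BOUND = "hard-support-bound"


@dataclass(frozen=True)
class TruncationSpec:
    """How the CMP series (and pmf support) is made finite.

    In ``series-truncation`` mode the sum over ``r = 0..k`` approximates the
    infinite series; in ``hard-support-bound`` mode counts cannot exceed
    ``k`` and the distribution is genuinely supported on ``{0..k}``.
    """

    mode: Literal["series-truncation", "hard-support-bound"] = SERIES
    k: int = DEFAULT_K

    def __post_init__(self):
        if self.mode not in (SERIES, BOUND):
            raise InvalidArgumentError(f"unknown truncation mode {self.mode!r}")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise InvalidArgumentError(f"truncation k must be a positive integer, got {self.k!r}")

    @classmethod
    def series(cls, k: int = DEFAULT_K) -> "TruncationSpec":
        return cls(SERIES, int(k))

    @classmethod
    def bound(cls, y_tau: int) -> "TruncationSpec":
        return cls(BOUND, int(y_tau))


def default_truncation(mu: float) -> TruncationSpec:
    """Series truncation at ``max(60, ceil(2 mu))`` terms."""
    return TruncationSpec.series(max(DEFAULT_K, math.ceil(2.0 * float(mu))))


@dataclass(frozen=True)
class MPCMPSpec:
    """A single MPCMP distribution: mean ``mu > 0``, dispersion ``nu >= 0``."""

    mu: float
    nu: float
    truncation: TruncationSpec = field(default_factory=TruncationSpec)

    def __post_init__(self):
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise InvalidArgumentError(f"mu must be positive and finite, got {self.mu!r}")
        if not (np.isfinite(self.nu) and self.nu >= 0):
            raise InvalidArgumentError(f"nu must be non-negative and finite, got {self.nu!r}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.truncation.k + 1)


@dataclass(frozen=True)
class RatePair:
    """A solved rate: ``log lambda`` with its matching ``log G(lambda, nu)``."""

    log_lambda: float
    log_G: float

    def __post_init__(self):
        if not (np.isfinite(self.log_lambda) and np.isfinite(self.log_G)):
            raise InvalidArgumentError(
                f"RatePair entries must be finite, got ({self.log_lambda!r}, {self.log_G!r})"
            )


def _validate(log_lambda, nu, trunc: TruncationSpec):
    log_lambda = np.asarray(log_lambda, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if not np.all(np.isfinite(log_lambda)):
        raise InvalidArgumentError("log_lambda must be finite")
    if not np.all(np.isfinite(nu)) or np.any(nu < 0):
        raise InvalidArgumentError("nu must be finite and non-negative")
    if trunc.k < 1:
        raise InvalidArgumentError("truncation k must be >= 1")
    return log_lambda, nu


def log_weights(log_lambda, nu, k: int) -> np.ndarray:
    """Unnormalised log pmf terms ``r log(lambda) - nu log(r!)`` for r = 0..k.

    Broadcasts over leading dimensions of ``log_lambda``/``nu``; the series
    index is the trailing axis.
    """
    r = np.arange(k + 1, dtype=float)
    log_lambda = np.asarray(log_lambda, dtype=float)[..., None]
    nu = np.asarray(nu, dtype=float)[..., None]
    return r * log_lambda - nu * gammaln(r + 1.0)


def log_normalising_constant(log_lambda, nu, trunc: TruncationSpec):
    """``log G(lambda, nu)`` = log-sum-exp of the truncated series.

    Stable for ``log lambda`` at least up to 50 and ``k`` into the hundreds:
    everything stays in log space until the final reduction.
    """
    log_lambda, nu = _validate(log_lambda, nu, trunc)
    out = logsumexp(log_weights(log_lambda, nu, trunc.k), axis=-1)
    return float(out) if out.ndim == 0 else out


def moments(log_lambda, nu, k: int):
    """Return ``(log_G, mean, variance)`` of the truncated CMP, vectorised.

    The mean and variance are the first two moments of the *truncated* pmf,
    i.e. exactly the quantities the mean-constraint solvers need
    (``d mean / d log lambda = variance``).
    """
    lw = log_weights(log_lambda, nu, k)
    log_G = logsumexp(lw, axis=-1, keepdims=True)
    p = np.exp(lw - log_G)
    r = np.arange(k + 1, dtype=float)
    mean = p @ r
    second = p @ (r * r)
    var = second - mean * mean
    return np.squeeze(log_G, axis=-1), mean, var


def mpcmp_mean(log_lambda, nu, trunc: TruncationSpec):
    """Mean ``sum_r r Pr(r)`` under the same truncation as the constant."""
    log_lambda, nu = _validate(log_lambda, nu, trunc)
    _, mean, _ = moments(log_lambda, nu, trunc.k)
    return float(mean) if np.ndim(mean) == 0 else mean


def mpcmp_log_pmf(y, spec: MPCMPSpec, rate: RatePair):
    """Log pmf ``y log lambda - nu log y! - log G`` at a solved rate."""
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.issubdtype(y_arr.dtype, np.integer):
        raise InvalidArgumentError("y must be non-negative integer(s)")
    if spec.truncation.mode == BOUND and np.any(y_arr > spec.truncation.k):
        raise InvalidArgumentError(
            f"y exceeds the hard support bound {spec.truncation.k}"
        )
    out = (
        y_arr * rate.log_lambda
        - spec.nu * gammaln(y_arr + 1.0)
        - rate.log_G
    )
    return float(out) if np.ndim(out) == 0 else out


def mpcmp_pmf_vector(spec: MPCMPSpec, rate: RatePair) -> np.ndarray:
    """The full pmf over the truncated support ``{0..k}`` (sums to one)."""
    lw = log_weights(rate.log_lambda, spec.nu, spec.truncation.k)
    return np.exp(lw - logsumexp(lw))


def mpcmp_variance(spec: MPCMPSpec, rate: RatePair) -> float:
    """Second central moment under the truncated pmf.

    Below the mean for ``nu > 1`` (underdispersion), above it for ``nu < 1``.
    """
    _, _, var = moments(rate.log_lambda, spec.nu, spec.truncation.k)
    return float(var)


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rmpcmp(n: int, spec: MPCMPSpec, rate: RatePair, seed) -> np.ndarray:
    """Draw ``n`` variates by CDF inversion on the truncated support."""
    if not n >= 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = _as_generator(seed)
    cdf = np.cumsum(mpcmp_pmf_vector(spec, rate))
    u = rng.random(int(n))
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def rmpcmp_rowwise(log_lambda, nu, k: int, rng: np.random.Generator) -> np.ndarray:
    """One count per row for heterogeneous ``(lambda_i, nu_i)``, by inversion.

    Used by the scenario generators where every observation may carry its own
    mean and dispersion; rows are independent.
    """
    lw = log_weights(log_lambda, nu, k)
    cdf = np.cumsum(np.exp(lw - logsumexp(lw, axis=-1, keepdims=True)), axis=-1)
    u = rng.random(cdf.shape[0])
    return (u[:, None] > cdf).sum(axis=1).astype(np.int64)
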