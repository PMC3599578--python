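"""The (restricted) generalized Poisson distribution.

The generalized Poisson (GP) distribution is a two-parameter count family

.. math::

    f(y; \\mu, \\alpha) = \\left(\\frac{\\mu}{1+\\alpha\\mu}\\right)^y
        \\frac{(1+\\alpha y)^{y-1}}{y!}
        \\exp\\!\\left(-\\frac{\\mu(1+\\alpha y)}{1+\\alpha\\mu}\\right),
    \\qquad y = 0, 1, 2, \\ldots

with mean :math:`\\mu` and variance :math:`\\mu(1+\\alpha\\mu)^2`.  At
``alpha == 0`` it reduces exactly to the Poisson distribution; ``alpha > 0``
gives over-dispersion (variance > mean) and ``alpha < 0`` under-dispersion
(variance < mean), the regime of family-level counts of malnourished
children.

For negative ``alpha`` the factor ``(1 + alpha*y)`` changes sign at
``y = -1/alpha``: the density is only defined on the finite support
``{0, ..., y_max}`` with ``1 + alpha*y_max > 0``.  The pmf is taken to be
exactly zero beyond that point, which leaves a (typically tiny) mass
deficiency; :func:`gp_total_mass` quantifies it and the sampler
renormalizes over the finite support so that draws form a proper
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import DataError, DomainError

__all__ = [
    "UNBOUNDED",
    "GPParams",
    "gp_pmf",
    "gp_mean_var",
    "gp_support_max",
    "gp_total_mass",
    "gp_sample",
    "sample_counts",
]

#: Marker returned by :func:`gp_support_max` when the support is infinite.
UNBOUNDED = math.inf

_TAIL_TOL = 1e-12


@dataclass(frozen=True)
class GPParams:
    """Parameters of one GP distribution.

    Parameters
    ----------
    mu : float
        Expected count per family; must be positive.
    alpha : float
        Dispersion parameter (dimensionless).  ``1 + alpha*mu`` must be
        positive for the density to be defined at the mean.
    """

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise DomainError(f"mu must be a positive finite number, got {self.mu!r}")
        if not np.isfinite(self.alpha):
            raise DomainError(f"alpha must be finite, got {self.alpha!r}")
        if 1.0 + self.alpha * self.mu <= 0:
            raise DomainError(
                f"1 + alpha*mu must be positive, got {1.0 + self.alpha * self.mu!r} "
                f"(mu={self.mu}, alpha={self.alpha})"
            )


def gp_support_max(params: GPParams) -> float:
    """Largest integer in the support, or :data:`UNBOUNDED` for ``alpha >= 0``."""
    if params.alpha >= 0:
        return UNBOUNDED
    # largest integer y with 1 + alpha*y > 0, i.e. y < -1/alpha
    bound = -1.0 / params.alpha
    if math.isinf(bound):  # subnormal alpha: support is astronomically large
        return UNBOUNDED
    y = math.floor(bound)
    if 1.0 + params.alpha * y <= 0:  # -1/alpha landed on (or fp-near) an integer
        y -= 1
    return float(y)


def _logpmf_vector(y: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """Log pmf on the support; y must already satisfy 1 + alpha*y > 0."""
    y = np.asarray(y, dtype=float)
    one_am = 1.0 + alpha * mu
    one_ay = 1.0 + alpha * y
    return (
        y * (np.log(mu) - np.log(one_am))
        + (y - 1.0) * np.log(one_ay)
        - mu * one_ay / one_am
        - gammaln(y + 1.0)
    )


def gp_pmf(y: int, params: GPParams) -> float:
    """Probability of observing the count ``y``.

    Computed on the log scale (with ``lgamma`` for the factorial) and
    exactly zero for ``y`` outside the finite support when ``alpha < 0``.
    """
    if isinstance(y, bool) or not (
        isinstance(y, (int, np.integer))
        or (isinstance(y, float) and float(y).is_integer())
    ):
        raise DataError(f"y must be a non-negative integer, got {y!r}")
    y = int(y)
    if y < 0:
        raise DataError(f"y must be a non-negative integer, got {y!r}")
    if 1.0 + params.alpha * y <= 0:
        return 0.0
    return float(np.exp(_logpmf_vector(np.array([y]), params.mu, params.alpha)[0]))


def gp_mean_var(params: GPParams) -> tuple[float, float]:
    """Mean and variance: ``(mu, mu*(1+alpha*mu)**2)``."""
    mu, alpha = params.mu, params.alpha
    return mu, mu * (1.0 + alpha * mu) ** 2


def _support_grid(params: GPParams, cap: int) -> np.ndarray:
    smax = gp_support_max(params)
    top = cap if smax is UNBOUNDED or math.isinf(smax) else int(min(smax, cap))
    return np.arange(0, top + 1)


def gp_total_mass(params: GPParams, cap: int = 1000) -> float:
    """Total probability over the support (capped at ``cap`` for ``alpha >= 0``).

    For ``alpha >= 0`` the sum approaches 1 as ``cap`` grows.  For
    ``alpha < 0`` the support is finite and the sum may fall slightly
    short of 1 — the known truncation deficiency of the GP family —
    and is reported as-is so callers can decide whether to renormalize.
    """
    ys = _support_grid(params, cap)
    return float(np.exp(_logpmf_vector(ys, params.mu, params.alpha)).sum())


def _pmf_table(mu: float, alpha: float, cap: int = 1000) -> np.ndarray:
    """Renormalized pmf over {0..top} suitable for inversion sampling."""
    params = GPParams(mu, alpha)
    if alpha < 0:
        ys = _support_grid(params, cap)
        p = np.exp(_logpmf_vector(ys, mu, alpha))
    else:
        top = 32
        while True:
            ys = np.arange(0, top + 1)
            p = np.exp(_logpmf_vector(ys, mu, alpha))
            if 1.0 - p.sum() < _TAIL_TOL or top >= cap:
                break
            top = min(2 * top, cap)
    return p / p.sum()


def gp_sample(
    params: GPParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. counts by inversion of the cumulative pmf.

    For ``alpha < 0`` the pmf is renormalized over its finite support, so
    the sampler is a proper distribution.  Identical seeds give identical
    output.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise DataError(f"n must be a positive integer, got {n!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _pmf_table(params.mu, params.alpha)
    cdf = np.cumsum(p)
    u = rng.random(int(n))
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def sample_counts(
    mu: np.ndarray, alpha: float, rng: np.random.Generator, cap: int = 1000
) -> np.ndarray:
    """Vectorized GP draws with one mean per observation (shared ``alpha``).

    Used by the synthetic-data generator where every family has its own
    ``mu_i = exp(x_i beta)``.  Each row's pmf is renormalized over the
    support before inversion.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(1.0 + alpha * mu <= 0):
        bad = int(np.argmin(1.0 + alpha * mu))
        raise DomainError(
            f"infeasible (mu, alpha) at index {bad}: mu={mu[bad]}, alpha={alpha}"
        )
    if alpha < 0:
        top = int(min(gp_support_max(GPParams(float(mu.max()), alpha)), cap))
    else:
        # expand until the largest-mean row has negligible tail mass
        top = 32
        while top < cap:
            tail = 1.0 - np.exp(
                _logpmf_vector(np.arange(0, top + 1), float(mu.max()), alpha)
            ).sum()
            if tail < _TAIL_TOL:
                break
            top = min(2 * top, cap)
    ys = np.arange(0, top + 1, dtype=float)
    one_am = 1.0 + alpha * mu[:, None]
    one_ay = 1.0 + alpha * ys[None, :]
    logp = (
        ys[None, :] * (np.log(mu[:, None]) - np.log(one_am))
        + (ys[None, :] - 1.0) * np.log(one_ay)
        - mu[:, None] * one_ay / one_am
        - gammaln(ys + 1.0)[None, :]
    )
    p = np.exp(logp)
    cdf = np.cumsum(p, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((mu.shape[0], 1))
    return (cdf < u).sum(axis=1).astype(np.int64)
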