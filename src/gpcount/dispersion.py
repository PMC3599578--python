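"""Dispersion diagnostics for raw count vectors.

Before fitting a count regression one has to decide between the standard
Poisson model (variance = mean) and the generalized Poisson model.  This
module implements the Consul–Jain moment estimators

.. math::

    \\hat\\mu = \\sqrt{\\bar y^3 / s^2}, \\qquad
    \\hat\\alpha = 1 - \\sqrt{\\bar y / s^2},

their asymptotic variances, and the Wald-type Z test of
``H0: alpha = 0`` against the two-sided alternative.  A negative
``alpha_hat`` (sample variance below the sample mean) indicates
under-dispersion and motivates generalized Poisson regression over the
standard Poisson model.

Note that these moment estimators live in the Consul–Jain
parametrization of the GP family: at the population level they converge
to ``theta = mu/(1+alpha*mu)`` and ``lambda = alpha*mu/(1+alpha*mu)``
rather than to the regression-scale ``(mu, alpha)`` themselves (the two
parametrizations coincide in sign and approximately in magnitude for
small counts).  The estimators are implemented exactly in the printed
form; :func:`alpha_from_meanvar` offers the regression-parametrization
analogue, used only as an optimizer starting value.

The closed algebraic form of the published asymptotic variances is not
recoverable from the source material; :func:`moment_estimator_variances`
is a delta-method reconstruction from the known central moments of the
GP family (validated against Monte Carlo and against the exact Poisson
limit ``V(alpha_hat) = 1/(2n)``), and :func:`dispersion_wald_test`
accepts any caller-supplied variance so a known variance can be used
directly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import DataError

__all__ = [
    "MomentEstimates",
    "DispersionTestResult",
    "moment_estimates",
    "moment_estimates_from_moments",
    "moment_estimator_variances",
    "alpha_from_meanvar",
    "dispersion_wald_test",
    "read_counts",
]


@dataclass(frozen=True)
class MomentEstimates:
    """Sample moments plus moment estimators and their asymptotic variances."""

    n: int
    y_bar: float
    s2: float
    mu_hat: float
    alpha_hat: float
    var_mu_hat: float
    var_alpha_hat: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DispersionTestResult:
    """Wald Z test of H0: alpha = 0."""

    z: float
    p_value: float
    reject_h0: bool
    direction: str  # "under-dispersion" | "over-dispersion" | "equi-dispersion"
    level: float

    def to_dict(self) -> dict:
        return asdict(self)


def moment_estimator_variances(
    mu_hat: float, alpha_hat: float, n: int
) -> tuple[float, float]:
    """Delta-method asymptotic variances of the moment estimators.

    Writing the estimators as smooth functions of the sample mean ``m``
    and sample variance ``v`` and using the GP central moments in the
    Consul parametrization ``theta = mu_hat``, ``lambda = alpha_hat``:

    .. math::

        m = \\theta/(1-\\lambda),\\quad
        \\mu_2 = \\theta/(1-\\lambda)^3,\\quad
        \\mu_3 = \\theta(1+2\\lambda)/(1-\\lambda)^5,

        \\mu_4 = 3\\theta^2/(1-\\lambda)^6
              + \\theta(1+8\\lambda+6\\lambda^2)/(1-\\lambda)^7,

    with ``n Cov(m, v) -> mu_3`` and ``n Var(v) -> mu_4 - mu_2^2``.
    At ``lambda = 0`` (Poisson) this reduces to ``V(alpha_hat) = 1/(2n)``.
    """
    if n < 2:
        raise DataError(f"n must be at least 2, got {n}")
    theta, lam = float(mu_hat), float(alpha_hat)
    om = 1.0 - lam
    m = theta / om
    mu2 = theta / om**3
    mu3 = theta * (1.0 + 2.0 * lam) / om**5
    mu4 = 3.0 * theta**2 / om**6 + theta * (1.0 + 8.0 * lam + 6.0 * lam**2) / om**7
    var_v = mu4 - mu2**2
    # gradients of alpha_hat = 1 - sqrt(m/v) and mu_hat = sqrt(m^3/v)
    ga_m = -0.5 / np.sqrt(m * mu2)
    ga_v = 0.5 * np.sqrt(m) / mu2**1.5
    gm_m = 1.5 * np.sqrt(m / mu2)
    gm_v = -0.5 * m**1.5 / mu2**1.5
    var_alpha = (ga_m**2 * mu2 + ga_v**2 * var_v + 2.0 * ga_m * ga_v * mu3) / n
    var_mu = (gm_m**2 * mu2 + gm_v**2 * var_v + 2.0 * gm_m * gm_v * mu3) / n
    return float(var_mu), float(var_alpha)


def moment_estimates_from_moments(y_bar: float, s2: float, n: int) -> MomentEstimates:
    """Moment estimators from pre-computed sample mean and variance."""
    if not (np.isfinite(y_bar) and y_bar > 0):
        raise DataError(f"sample mean must be positive, got {y_bar!r}")
    if not (np.isfinite(s2) and s2 > 0):
        raise DataError(f"sample variance must be positive, got {s2!r}")
    mu_hat = float(np.sqrt(y_bar**3 / s2))
    alpha_hat = float(1.0 - np.sqrt(y_bar / s2))
    var_mu, var_alpha = moment_estimator_variances(mu_hat, alpha_hat, n)
    return MomentEstimates(
        n=int(n),
        y_bar=float(y_bar),
        s2=float(s2),
        mu_hat=mu_hat,
        alpha_hat=alpha_hat,
        var_mu_hat=var_mu,
        var_alpha_hat=var_alpha,
    )


def moment_estimates(counts) -> MomentEstimates:
    """Moment estimators from a raw count vector.

    The sample variance uses the ``n - 1`` denominator.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise DataError("counts must be a 1-d vector with at least 2 elements")
    if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y != np.round(y)):
        raise DataError("counts must be non-negative integers")
    s2 = float(y.var(ddof=1))
    if s2 <= 0:
        raise DataError("counts have zero variance; dispersion is undefined")
    return moment_estimates_from_moments(float(y.mean()), s2, y.size)


def alpha_from_meanvar(y_bar: float, s2: float) -> float:
    """Regression-parametrization moment estimate of the dispersion.

    Solves ``s2 = y_bar*(1 + alpha*y_bar)^2`` for alpha:
    ``(sqrt(s2/y_bar) - 1)/y_bar``.  Convenience starting value for the
    maximum-likelihood fit; not part of the printed-estimator path.
    """
    if y_bar <= 0 or s2 <= 0:
        raise DataError("y_bar and s2 must be positive")
    return float((np.sqrt(s2 / y_bar) - 1.0) / y_bar)


def dispersion_wald_test(
    alpha_hat: float, var_alpha_hat: float, level: float = 0.05
) -> DispersionTestResult:
    """Two-sided Wald Z test of H0: alpha = 0.

    ``z = alpha_hat / sqrt(var_alpha_hat)`` referred to the standard
    normal.  Rejecting H0 with ``alpha_hat < 0`` (under-dispersion)
    recommends the generalized Poisson model over standard Poisson.
    """
    if not (np.isfinite(var_alpha_hat) and var_alpha_hat > 0):
        raise DataError(f"var_alpha_hat must be positive, got {var_alpha_hat!r}")
    if not 0 < level < 1:
        raise DataError(f"level must be in (0, 1), got {level!r}")
    z = float(alpha_hat / np.sqrt(var_alpha_hat))
    p = float(2.0 * stats.norm.sf(abs(z)))
    if alpha_hat < 0:
        direction = "under-dispersion"
    elif alpha_hat > 0:
        direction = "over-dispersion"
    else:
        direction = "equi-dispersion"
    return DispersionTestResult(
        z=z, p_value=p, reject_h0=bool(p < level), direction=direction, level=level
    )


def read_counts(path: str | Path) -> np.ndarray:
    """Read a single-column vector of counts from delimited text.

    A non-numeric first line is treated as a header and skipped.
    """
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise DataError(f"{path}: empty counts file")
    try:
        float(lines[0].strip())
    except ValueError:
        lines = lines[1:]
    try:
        return np.array([int(float(ln.strip())) for ln in lines if ln.strip()])
    except ValueError as exc:
        raise DataError(f"{path}: could not parse counts ({exc})") from exc


def write_test_json(
    path: str | Path, est: MomentEstimates, test: DispersionTestResult
) -> None:
    """Write estimates + test result as a small JSON document."""
    payload = {"estimates": est.to_dict(), "test": test.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
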