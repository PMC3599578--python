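"""Maximum-likelihood generalized Poisson regression (GPR).

The model: counts :math:`y_i` are GP with mean
:math:`\\mu_i = \\exp(x_i\\beta)` (log link) and a shared dispersion
parameter :math:`\\alpha`; the log-likelihood is

.. math::

    \\ell(\\beta, \\alpha) = \\sum_i \\Big[
        y_i \\log\\frac{\\mu_i}{1+\\alpha\\mu_i}
        + (y_i - 1)\\log(1+\\alpha y_i)
        - \\frac{\\mu_i(1+\\alpha y_i)}{1+\\alpha\\mu_i}
        - \\log y_i! \\Big].

``(beta, alpha)`` are estimated jointly by maximizing the likelihood
(L-BFGS-B with the analytic gradient); ``alpha`` is box-constrained to
keep ``1 + alpha*y_i > 0`` for every observed count, and points where
``1 + alpha*mu_i <= 0`` are handled with a large-penalty sentinel so the
line search can back off.  Standard errors come from the numerically
differentiated observed information at the optimum.  At ``alpha = 0``
the model is exactly standard Poisson regression, which
:func:`fit_poisson` fits through the same code path.

Effects are reported as incidence rate ratios (IRR): ``exp(beta_j)`` is
the multiplicative change in the expected number of malnourished
children per family relative to the reference category, with Wald
chi-square tests (1 df) and 95% CIs ``exp(beta_j ± 1.96 SE_j)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

from .dispersion import alpha_from_meanvar
from .exceptions import (
    ConvergenceError,
    DataError,
    RankDeficiencyError,
    SingularInformationError,
)

__all__ = [
    "Categorical",
    "DesignSpec",
    "FitOptions",
    "GPRFit",
    "build_design_matrix",
    "gpr_loglik",
    "fit_gpr",
    "fit_poisson",
    "coefficient_report",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e12
_Z975 = 1.96  # matches the reported symmetric-on-log-scale 95% intervals


@dataclass(frozen=True)
class Categorical:
    """One categorical predictor with an ordered level list and a reference."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise DataError(
                f"predictor {self.name!r}: reference {self.reference!r} "
                f"not among levels {self.levels}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise DataError(f"predictor {self.name!r}: duplicate levels")


@dataclass(frozen=True)
class DesignSpec:
    """Model specification: categorical and continuous predictors."""

    categorical: tuple[Categorical, ...] = ()
    continuous: tuple[str, ...] = ()
    intercept: bool = True

    def __post_init__(self) -> None:
        names = [c.name for c in self.categorical] + list(self.continuous)
        if len(set(names)) != len(names):
            raise DataError(f"duplicate predictor names in design: {names}")

    @property
    def predictor_names(self) -> list[str]:
        return [c.name for c in self.categorical] + list(self.continuous)

    def subset(self, keep: list[str]) -> "DesignSpec":
        """Restrict the design to the named predictors (order preserved)."""
        return DesignSpec(
            categorical=tuple(c for c in self.categorical if c.name in keep),
            continuous=tuple(c for c in self.continuous if c in keep),
            intercept=self.intercept,
        )

    def to_dict(self) -> dict:
        return {
            "categorical": [
                {"name": c.name, "levels": list(c.levels), "reference": c.reference}
                for c in self.categorical
            ],
            "continuous": list(self.continuous),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            categorical=tuple(
                Categorical(c["name"], tuple(c["levels"]), c["reference"])
                for c in d.get("categorical", ())
            ),
            continuous=tuple(d.get("continuous", ())),
            intercept=bool(d.get("intercept", True)),
        )


def build_design_matrix(
    records: pd.DataFrame, spec: DesignSpec, response: str = "n_malnourished"
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Indicator-coded design matrix, column labels, and response vector.

    One indicator column per non-reference level of each categorical
    predictor, continuous columns passed through, and a leading intercept
    column of ones.  Rows with a missing value in any used column are
    dropped (complete-case analysis) with a logged count.
    """
    needed = spec.predictor_names + [response]
    for col in needed:
        if col not in records.columns:
            raise DataError(f"records are missing required field {col!r}")
    df = records[needed]
    mask = df.notna().all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d records", n_dropped, len(df))
    df = df.loc[mask]
    if df.empty:
        raise DataError("no complete-case records remain")

    y = df[response].to_numpy()
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise DataError(f"response {response!r} must hold non-negative integers")
    y = y.astype(np.int64)

    cols: list[np.ndarray] = []
    labels: list[str] = []
    if spec.intercept:
        cols.append(np.ones(len(df)))
        labels.append("Intercept")
    for cat in spec.categorical:
        values = df[cat.name].astype(str)
        known = set(cat.levels)
        bad = values[~values.isin(known)]
        if not bad.empty:
            idx = bad.index[0]
            raise DataError(
                f"record {idx}, field {cat.name!r}: unknown level {bad.iloc[0]!r} "
                f"(expected one of {cat.levels})"
            )
        for level in cat.levels:
            if level == cat.reference:
                continue
            cols.append((values == level).to_numpy(dtype=float))
            labels.append(f"{cat.name}[{level}]")
    for name in spec.continuous:
        cols.append(df[name].to_numpy(dtype=float))
        labels.append(name)
    X = np.column_stack(cols)
    return X, labels, y


# ---------------------------------------------------------------------------
# likelihood


def _negll_and_grad(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, lfact: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient over (beta..., alpha)."""
    beta, alpha = params[:-1], params[-1]
    eta = X @ beta
    mu = np.exp(eta)
    one_am = 1.0 + alpha * mu
    one_ay = 1.0 + alpha * y
    if np.any(one_am <= 1e-10) or np.any(one_ay <= 1e-10):
        # penalty sentinel keeps L-BFGS-B's line search recoverable
        viol = float(np.sum(np.maximum(0.0, 1e-10 - one_am))) + float(
            np.sum(np.maximum(0.0, 1e-10 - one_ay))
        )
        return _PENALTY * (1.0 + viol), np.zeros_like(params)
    ll = np.sum(
        y * (eta - np.log(one_am))
        + (y - 1.0) * np.log(one_ay)
        - mu * one_ay / one_am
        - lfact
    )
    # d ll / d mu_i, then chain rule through mu = exp(X beta)
    dmu = y / mu - y * alpha / one_am - one_ay / one_am**2
    gbeta = X.T @ (dmu * mu)
    dalpha = np.sum(
        -y * mu / one_am
        + y * (y - 1.0) / one_ay
        - mu * (y * one_am - mu * one_ay) / one_am**2
    )
    grad = np.append(gbeta, dalpha)
    return -ll, -grad


def gpr_loglik(beta, alpha: float, design: np.ndarray, y) -> float:
    """GP regression log-likelihood at ``(beta, alpha)``.

    Returns ``-inf`` (a sentinel, not an error) when the point is
    infeasible, i.e. some ``1 + alpha*mu_i <= 0`` or ``1 + alpha*y_i <= 0``.
    At ``alpha = 0`` this is exactly the Poisson log-likelihood.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if beta.shape[0] != X.shape[1]:
        raise DataError(
            f"beta has {beta.shape[0]} entries but design has {X.shape[1]} columns"
        )
    mu = np.exp(X @ beta)
    if np.any(1.0 + alpha * mu <= 0) or np.any(1.0 + alpha * y <= 0):
        return -np.inf
    lfact = gammaln(y + 1.0)
    nll, _ = _negll_and_grad(np.append(beta, alpha), X, y, lfact)
    return -float(nll)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_gpr` / :func:`fit_poisson`."""

    max_iter: int = 500
    ftol: float = 1e-9
    gtol: float = 1e-6
    alpha_margin: float = 1e-6
    hessian_step: float = 1e-5


@dataclass
class GPRFit:
    """A fitted GP (or Poisson) regression."""

    beta: np.ndarray
    alpha: float
    covariance: np.ndarray  # (k+1)x(k+1) for GPR, kxk for alpha pinned to 0
    loglik: float
    converged: bool
    n_obs: int
    iterations: int
    labels: list[str] = field(default_factory=list)
    alpha_fixed: bool = False

    @property
    def beta_se(self) -> np.ndarray:
        k = self.beta.shape[0]
        return np.sqrt(np.diag(self.covariance)[:k])

    @property
    def alpha_se(self) -> float:
        if self.alpha_fixed:
            return float("nan")
        return float(np.sqrt(self.covariance[-1, -1]))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "beta": [float(b) for b in self.beta],
            "beta_se": [float(s) for s in self.beta_se],
            "alpha": float(self.alpha),
            "alpha_se": None if self.alpha_fixed else float(self.alpha_se),
            "alpha_fixed": self.alpha_fixed,
            "loglik": float(self.loglik),
            "converged": self.converged,
            "n_obs": self.n_obs,
            "iterations": self.iterations,
        }


def _check_design(X: np.ndarray, y: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank-deficient ({X.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(X)})"
        )
    if np.all(y == y[0]):
        raise DataError("response is degenerate (all counts identical)")


def _poisson_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    try:
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return np.asarray(glm.params, dtype=float)
    except Exception:  # pragma: no cover - statsmodels failure fallback
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(max(y.mean(), 1e-8))
        return beta0


def _numeric_hessian(fun, x: np.ndarray, step: float) -> np.ndarray:
    """Central-difference Hessian of a scalar function via its gradient."""
    k = x.shape[0]
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = fun(xp)
        _, gm = fun(xm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _covariance(fun, x: np.ndarray, step: float) -> np.ndarray:
    H = _numeric_hessian(fun, x, step)  # Hessian of the NEGATIVE loglik
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(f"observed information is singular: {exc}")
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        raise SingularInformationError(
            "observed information is not positive definite at the optimum"
        )
    return cov


def fit_gpr(
    design: np.ndarray,
    y,
    options: FitOptions | None = None,
    labels: list[str] | None = None,
) -> GPRFit:
    """Joint maximum-likelihood fit of ``(beta, alpha)``.

    beta starts at the Poisson GLM estimate, alpha at the
    regression-parametrization moment estimate clipped into the feasible
    box ``alpha > -1/max(y)``.
    """
    opts = options or FitOptions()
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    _check_design(X, y)
    lfact = gammaln(y + 1.0)

    beta0 = _poisson_start(X, y)
    ymax = int(y.max())
    alpha_low = -1.0 / ymax + opts.alpha_margin if ymax > 0 else -np.inf
    a0 = alpha_from_meanvar(float(y.mean()), float(y.var(ddof=1)))
    a0 = float(np.clip(a0, alpha_low + opts.alpha_margin, 5.0))
    x0 = np.append(beta0, a0)

    def fun(p):
        return _negll_and_grad(p, X, y, lfact)

    bounds = [(None, None)] * X.shape[1] + [(alpha_low, None)]
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": opts.gtol},
    )
    if not res.success or not np.isfinite(res.fun):
        raise ConvergenceError(
            f"GPR fit did not converge after {res.nit} iterations: {res.message}"
        )
    cov = _covariance(fun, res.x, opts.hessian_step)
    return GPRFit(
        beta=res.x[:-1].copy(),
        alpha=float(res.x[-1]),
        covariance=cov,
        loglik=-float(res.fun),
        converged=True,
        n_obs=int(y.size),
        iterations=int(res.nit),
        labels=list(labels or []),
    )


def fit_poisson(
    design: np.ndarray,
    y,
    options: FitOptions | None = None,
    labels: list[str] | None = None,
) -> GPRFit:
    """Standard Poisson regression: the GP model with alpha pinned to 0."""
    opts = options or FitOptions()
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    _check_design(X, y)
    lfact = gammaln(y + 1.0)

    def fun(beta):
        nll, grad = _negll_and_grad(np.append(beta, 0.0), X, y, lfact)
        return nll, grad[:-1]

    res = optimize.minimize(
        fun,
        _poisson_start(X, y),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": opts.gtol},
    )
    if not res.success or not np.isfinite(res.fun):
        raise ConvergenceError(
            f"Poisson fit did not converge after {res.nit} iterations: {res.message}"
        )
    cov = _covariance(fun, res.x, opts.hessian_step)
    return GPRFit(
        beta=res.x.copy(),
        alpha=0.0,
        covariance=cov,
        loglik=-float(res.fun),
        converged=True,
        n_obs=int(y.size),
        iterations=int(res.nit),
        labels=list(labels or []),
        alpha_fixed=True,
    )


def coefficient_report(
    fit: GPRFit,
    labels: list[str] | None = None,
    spec: DesignSpec | None = None,
) -> pd.DataFrame:
    """Per-term estimates, Wald chi-squares, p-values, IRRs and 95% CIs.

    When a :class:`DesignSpec` is supplied, an explicit reference-level
    row (estimates blank, ``reference=True``) is appended after each
    categorical predictor's block, mirroring the conventional "(r)"
    presentation.
    """
    if not fit.converged:
        raise ConvergenceError("cannot report coefficients of a non-converged fit")
    labels = list(labels or fit.labels)
    if len(labels) != fit.beta.shape[0]:
        raise DataError(
            f"{len(labels)} labels for {fit.beta.shape[0]} fitted coefficients"
        )
    se = fit.beta_se
    rows = []
    for name, b, s in zip(labels, fit.beta, se):
        w = (b / s) ** 2
        rows.append(
            {
                "term": name,
                "estimate": float(b),
                "se": float(s),
                "wald_chi2": float(w),
                "p_value": float(stats.chi2.sf(w, df=1)),
                "irr": float(np.exp(b)),
                "irr_low": float(np.exp(b - _Z975 * s)),
                "irr_high": float(np.exp(b + _Z975 * s)),
                "reference": False,
            }
        )
    report = pd.DataFrame(rows)
    if spec is not None:
        blocks = []
        if spec.intercept:
            blocks.append(report[report["term"] == "Intercept"])
        for cat in spec.categorical:
            terms = [f"{cat.name}[{lv}]" for lv in cat.levels if lv != cat.reference]
            blocks.append(report[report["term"].isin(terms)])
            blocks.append(
                pd.DataFrame(
                    [{"term": f"{cat.name}[{cat.reference}]", "reference": True}]
                )
            )
        blocks.append(report[report["term"].isin(spec.continuous)])
        report = pd.concat(blocks, ignore_index=True)
    return report
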