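"""Seeded synthetic survey data with known ground truth.

The generator emulates the structure of a household-survey analysis of
under-five malnutrition: family-level categorical covariates sampled
independently from reference marginals, a log-linear mean
``mu_i = exp(x_i beta)``, generalized Poisson counts with
under-dispersion, and (optionally) child-level weight-for-height
Z-score records consistent with each family's count so the outcome
builder can be round-tripped.

The intercept is calibrated in closed form so that the expected count
per family matches the reference mean (0.626 by default): since the
covariates are independent, ``E[exp(x beta)]`` factorizes into per-
predictor terms (a finite sum over levels, or the moment generating
function of the integer covariates), and the intercept is
``log(target) - log`` of that product.

Everything is driven by a single integer seed; identical configs give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import poisson, truncnorm

from . import study
from .distribution import sample_counts
from .exceptions import ConfigError, FitError
from .regression import DesignSpec, build_design_matrix, fit_gpr

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "calibrate_intercept",
    "generate_families",
    "generate_children",
    "parameter_recovery_experiment",
]


def _truncated_poisson_pmf(mean: float, cap: int) -> np.ndarray:
    """pmf of min(Poisson(mean), cap) on {0..cap} (tail mass folded into cap)."""
    p = poisson.pmf(np.arange(cap + 1), mean)
    p[-1] += poisson.sf(cap, mean)
    return p


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n_families: int = 1200
    marginals: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in study.TABLE_MARGINALS.items()
    })
    beta: dict = field(default_factory=lambda: dict(study.TRUE_BETA))
    intercept: Optional[float] = None  # None -> calibrated to target_mean_count
    alpha: float = study.TRUE_ALPHA
    target_mean_count: float = study.MEAN_COUNT
    # children ever born to a woman = 1 + capped-Poisson excess (mean 2.67)
    ever_born_excess_mean: float = study.EVER_BORN_MEAN - 1.0
    ever_born_excess_cap: int = 9
    died_mean: float = study.DIED_MEAN
    # under-five children per family = 1 + capped-Poisson excess; the
    # reference aggregates imply a mean of 0.626/0.169 = 3.70
    under5_excess_mean: float = study.MEAN_COUNT / study.CHILD_PREVALENCE - 1.0
    under5_excess_cap: int = 9
    seed: int = 0
    emit_children: bool = False
    # WHZ noise: (loc, scale, lower, upper) of truncated normals
    whz_malnourished: tuple = (-2.6, 0.45, -5.0, -2.0)
    whz_healthy: tuple = (-0.3, 0.95, -2.0, 5.0)

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be positive")
        for pred, levels in self.marginals.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"level probabilities of {pred!r} sum to {total}, not 1"
                )
            if any(p < 0 for p in levels.values()):
                raise ConfigError(f"negative probability in {pred!r}")


@dataclass
class SyntheticDataset:
    """Generated family (and optionally child) records plus provenance."""

    families: pd.DataFrame
    children: Optional[pd.DataFrame]
    config: SyntheticConfig


def calibrate_intercept(config: SyntheticConfig) -> float:
    """Intercept making E[mu] equal ``target_mean_count`` exactly.

    Uses the independence of the covariates:
    ``E[exp(x beta)] = prod_pred sum_level p(level) exp(beta(level))``
    times the MGFs of the two integer covariates.
    """
    log_factor = 0.0
    for pred, levels in config.marginals.items():
        log_factor += float(np.log(sum(
            p * np.exp(config.beta.get(f"{pred}[{lv}]", 0.0))
            for lv, p in levels.items()
        )))
    b_eb = config.beta.get("children_ever_born", 0.0)
    pmf = _truncated_poisson_pmf(config.ever_born_excess_mean, config.ever_born_excess_cap)
    log_factor += float(np.log(np.sum(
        pmf * np.exp(b_eb * (1.0 + np.arange(pmf.size)))
    )))
    b_d = config.beta.get("children_died", 0.0)
    # Poisson MGF: E[exp(t D)] = exp(mean*(e^t - 1))
    log_factor += config.died_mean * (np.exp(b_d) - 1.0)
    return float(np.log(config.target_mean_count) - log_factor)


def _linear_predictor(
    families: pd.DataFrame, config: SyntheticConfig, intercept: float
) -> np.ndarray:
    eta = np.full(len(families), intercept)
    for pred in config.marginals:
        levels = families[pred].to_numpy()
        lut = {lv: config.beta.get(f"{pred}[{lv}]", 0.0) for lv in config.marginals[pred]}
        eta += np.array([lut[lv] for lv in levels])
    eta += config.beta.get("children_ever_born", 0.0) * families["children_ever_born"].to_numpy()
    eta += config.beta.get("children_died", 0.0) * families["children_died"].to_numpy()
    return eta


def generate_families(config: SyntheticConfig) -> SyntheticDataset:
    """Sample family covariates, true means, and GP counts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_families
    data: dict = {"family_id": [f"F{i:06d}" for i in range(n)]}
    for pred, levels in config.marginals.items():
        names = list(levels.keys())
        data[pred] = rng.choice(names, size=n, p=np.array(list(levels.values())))
    eb_pmf = _truncated_poisson_pmf(config.ever_born_excess_mean, config.ever_born_excess_cap)
    data["children_ever_born"] = 1 + rng.choice(eb_pmf.size, size=n, p=eb_pmf)
    data["children_died"] = rng.poisson(config.died_mean, size=n)
    families = pd.DataFrame(data)

    intercept = config.intercept if config.intercept is not None else calibrate_intercept(config)
    mu = np.exp(_linear_predictor(families, config, intercept))
    feas = 1.0 + config.alpha * mu
    if np.any(feas <= 0):
        i = int(np.argmin(feas))
        raise ConfigError(
            "infeasible (mu, alpha) for covariate pattern "
            f"{families.iloc[i].to_dict()}: mu={mu[i]:.4f}, alpha={config.alpha}"
        )
    families["mu_true"] = mu
    families["n_malnourished"] = sample_counts(mu, config.alpha, rng)

    dataset = SyntheticDataset(families=families, children=None, config=config)
    if config.emit_children:
        dataset.children = generate_children(dataset, config)
    return dataset


def generate_children(
    dataset: SyntheticDataset, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Child-level WHZ records consistent with each family's count.

    Each family receives ``max(count, 1 + capped-Poisson excess)``
    under-five children; exactly ``count`` of them draw a WHZ below -2
    (truncated normal), the rest at or above -2.  Uses a child RNG
    stream derived from the config seed, so family and child generation
    are individually reproducible.
    """
    config = config or dataset.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    counts = dataset.families["n_malnourished"].to_numpy()
    u5_pmf = _truncated_poisson_pmf(config.under5_excess_mean, config.under5_excess_cap)
    n_children = 1 + rng.choice(u5_pmf.size, size=counts.size, p=u5_pmf)
    n_children = np.maximum(n_children, counts)

    total = int(n_children.sum())
    fam_idx = np.repeat(np.arange(counts.size), n_children)
    starts = np.concatenate(([0], np.cumsum(n_children)[:-1]))
    pos = np.arange(total) - np.repeat(starts, n_children)
    # the first `count` children of each family are flagged malnourished;
    # within-family child order carries no meaning
    malnourished = pos < counts[fam_idx]

    ages = rng.integers(0, 60, size=total)
    u = rng.random(total)
    lo_m, sc_m, a_m, b_m = config.whz_malnourished
    lo_h, sc_h, a_h, b_h = config.whz_healthy
    # clamp against fp rounding at the -2 boundary so the classification
    # of every generated child is unambiguous
    whz = np.where(
        malnourished,
        np.minimum(
            truncnorm.ppf(u, (a_m - lo_m) / sc_m, (b_m - lo_m) / sc_m, loc=lo_m, scale=sc_m),
            -2.0 - 1e-9,
        ),
        np.maximum(
            truncnorm.ppf(u, (a_h - lo_h) / sc_h, (b_h - lo_h) / sc_h, loc=lo_h, scale=sc_h),
            -2.0,
        ),
    )
    fam_ids = dataset.families["family_id"].to_numpy()
    return pd.DataFrame(
        {
            "child_id": [f"{fam_ids[i]}-C{p:02d}" for i, p in zip(fam_idx, pos)],
            "family_id": fam_ids[fam_idx],
            "whz": whz,
            "age_months": ages,
            "measured": True,
        }
    )


def parameter_recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    seed: int,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Generate -> fit -> score, replicated.

    Per replicate: draw a dataset, fit the GP regression, and record the
    error of every coefficient (and of alpha) together with whether the
    95% Wald CI covered the truth.  Returns one row per parameter with
    the true value, mean estimate, bias, RMSE, empirical coverage, and
    the number of successful / failed fits.  Fit failures are counted,
    not fatal.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be at least 1")
    design = design or study.model_design()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    intercept = config.intercept if config.intercept is not None else calibrate_intercept(config)
    probe = generate_families(replace(config, n_families=2, seed=0, emit_children=False))
    _, labels, _ = build_design_matrix(probe.families, design)
    truth = np.array(
        [intercept if lb == "Intercept" else config.beta.get(lb, 0.0) for lb in labels]
        + [config.alpha]
    )
    names = labels + ["alpha"]

    ests = np.full((n_replicates, len(names)), np.nan)
    covered = np.full((n_replicates, len(names)), np.nan)
    n_fail = 0
    for r, s in enumerate(rep_seeds):
        ds = generate_families(replace(config, seed=int(s), emit_children=False))
        X, labels_r, y = build_design_matrix(ds.families, design)
        try:
            fit = fit_gpr(X, y, labels=labels_r)
        except FitError:
            n_fail += 1
            continue
        est = np.append(fit.beta, fit.alpha)
        se = np.append(fit.beta_se, fit.alpha_se)
        ests[r] = est
        covered[r] = (np.abs(est - truth) <= 1.96 * se).astype(float)

    ok = ~np.isnan(ests[:, 0])
    report = pd.DataFrame(
        {
            "parameter": names,
            "true": truth,
            "mean_estimate": np.nanmean(ests, axis=0),
            "bias": np.nanmean(ests - truth[None, :], axis=0),
            "rmse": np.sqrt(np.nanmean((ests - truth[None, :]) ** 2, axis=0)),
            "mc_se": np.nanstd(ests, axis=0, ddof=1) / max(np.sqrt(ok.sum()), 1.0),
            "coverage": np.nanmean(covered, axis=0),
            "n_fit": int(ok.sum()),
            "n_fail": n_fail,
        }
    )
    return report
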