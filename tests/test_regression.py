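import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.discrete.discrete_model import GeneralizedPoisson

from gpcount import (
    GPParams,
    GPRFit,
    build_design_matrix,
    coefficient_report,
    fit_gpr,
    fit_poisson,
    gp_sample,
    gpr_loglik,
)
from gpcount.exceptions import DataError, RankDeficiencyError
from gpcount.regression import _negll_and_grad
from scipy.special import gammaln


class TestDesignMatrix:
    def test_single_indicator_for_binary_predictor(self, toy_families, toy_design):
        X, labels, y = build_design_matrix(toy_families, toy_design)
        urban = X[:, labels.index("residence[urban]")]
        assert urban.tolist() == [1, 0, 0, 1, 0, 0]

    def test_reference_quintile_gets_four_indicators(self, toy_families, toy_design):
        X, labels, _ = build_design_matrix(toy_families, toy_design)
        wealth_cols = [l for l in labels if l.startswith("wealth_index[")]
        assert wealth_cols == [
            "wealth_index[lowest]",
            "wealth_index[second]",
            "wealth_index[middle]",
            "wealth_index[fourth]",
        ]

    def test_all_reference_row_is_intercept_only(self, toy_design):
        df = pd.DataFrame(
            {
                "residence": ["rural"],
                "wealth_index": ["highest"],
                "children_ever_born": [0],
                "n_malnourished": [0],
            }
        )
        X, labels, _ = build_design_matrix(df, toy_design)
        assert labels[0] == "Intercept"
        assert X[0].tolist() == [1.0] + [0.0] * (len(labels) - 1)

    def test_unknown_level_names_record_and_field(self, toy_families, toy_design):
        bad = toy_families.copy()
        bad.loc[3, "residence"] = "suburban"
        with pytest.raises(DataError, match=r"record 3.*residence.*suburban"):
            build_design_matrix(bad, toy_design)

    def test_missing_field_rejected(self, toy_families, toy_design):
        with pytest.raises(DataError, match="wealth_index"):
            build_design_matrix(toy_families.drop(columns=["wealth_index"]), toy_design)

    def test_complete_case_drops_missing_rows(self, toy_families, toy_design):
        damaged = toy_families.copy()
        damaged.loc[1, "children_ever_born"] = np.nan
        X, _, y = build_design_matrix(damaged, toy_design)
        assert X.shape[0] == len(y) == len(toy_families) - 1


class TestLoglik:
    def test_poisson_reduction_single_observation(self):
        # y=0, mu=1, alpha=0: loglik = -mu
        assert gpr_loglik([0.0], 0.0, np.ones((1, 1)), [0]) == pytest.approx(-1.0)

    def test_hand_evaluated_gp_term(self):
        # y=2, mu=1, alpha=0.5: 2 log(1/1.5) + log 2 - 2/1.5 - log 2
        ll = gpr_loglik([0.0], 0.5, np.ones((1, 1)), [2])
        assert ll == pytest.approx(-2.1443, abs=1e-4)

    def test_matches_poisson_on_random_instances(self, rng):
        for _ in range(50):
            n, k = 20, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            beta = rng.normal(scale=0.3, size=k)
            y = rng.poisson(1.0, size=n)
            expected = float(stats.poisson.logpmf(y, np.exp(X @ beta)).sum())
            assert gpr_loglik(beta, 0.0, X, y) == pytest.approx(expected, abs=1e-10)

    def test_matches_statsmodels_generalized_poisson(self, rng):
        """Independent oracle: the mean-parametrized GP likelihood in
        statsmodels (variance mu*(1+alpha*mu)^2) evaluated at arbitrary
        feasible points."""
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(1.2, size=n)
        model = GeneralizedPoisson(y, X, p=2)
        for _ in range(20):
            beta = rng.normal(scale=0.2, size=2)
            alpha = rng.uniform(-0.2, 0.4)
            ours = gpr_loglik(beta, alpha, X, y)
            theirs = float(model.loglike(np.append(beta, alpha)))
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_infeasible_point_returns_negative_infinity(self):
        assert gpr_loglik([0.0], -0.4, np.ones((3, 1)), [0, 1, 3]) == -np.inf

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DataError):
            gpr_loglik([0.0, 1.0], 0.0, np.ones((2, 1)), [0, 1])

    def test_analytic_gradient_matches_finite_differences(self, rng):
        n, k = 30, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.poisson(1.0, size=n)
        lfact = gammaln(y + 1.0)
        params = np.append(rng.normal(scale=0.2, size=k), -0.1)
        _, grad = _negll_and_grad(params, X, y, lfact)
        num = optimize.approx_fprime(
            params, lambda p: _negll_and_grad(p, X, y, lfact)[0], 1e-7
        )
        assert np.allclose(grad, num, rtol=1e-4, atol=1e-5)


class TestFitting:
    def test_intercept_only_recovers_count_mean(self):
        y = gp_sample(GPParams(0.7, -0.25), 3000, seed=2)
        fit = fit_gpr(np.ones((y.size, 1)), y)
        assert np.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-4)
        for delta in (-0.1, 0.1):
            assert fit.loglik >= gpr_loglik(
                [fit.beta[0] + delta], fit.alpha, np.ones((y.size, 1)), y
            )

    def test_recovers_simulation_truth_within_three_se(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.4, n), rng.normal(size=n)])
        beta = np.array([-0.5, 0.4, 0.2])
        alpha = -0.2
        mu = np.exp(X @ beta)
        from gpcount.distribution import sample_counts

        y = sample_counts(mu, alpha, rng)
        fit = fit_gpr(X, y)
        assert np.all(np.abs(fit.beta - beta) < 3 * fit.beta_se)
        assert abs(fit.alpha - alpha) < 3 * fit.alpha_se

    def test_alpha_near_zero_on_poisson_data(self, rng):
        y = rng.poisson(0.8, size=5000)
        fit = fit_gpr(np.ones((y.size, 1)), y)
        assert abs(fit.alpha) < 0.03

    def test_poisson_fit_is_nested_in_gpr(self, rng):
        y = gp_sample(GPParams(0.7, -0.25), 2000, seed=8)
        X = np.ones((y.size, 1))
        gpr = fit_gpr(X, y)
        pois = fit_poisson(X, y)
        assert pois.alpha == 0.0
        assert gpr.loglik >= pois.loglik
        assert np.exp(pois.beta[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_poisson_fit_matches_glm_oracle(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n)])
        y = rng.poisson(np.exp(-0.3 + 0.4 * X[:, 1]))
        ours = fit_poisson(X, y)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(ours.beta, glm.params, atol=1e-6)
        assert np.allclose(ours.beta_se, glm.bse, atol=1e-4)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(RankDeficiencyError):
            fit_gpr(X, np.arange(10) % 2)

    def test_degenerate_response_rejected(self):
        with pytest.raises(DataError):
            fit_gpr(np.ones((10, 1)), np.zeros(10, dtype=int))


class TestCoefficientReport:
    def _dummy_fit(self, beta, se):
        k = len(beta)
        cov = np.zeros((k + 1, k + 1))
        cov[np.diag_indices(k)] = np.asarray(se) ** 2
        cov[-1, -1] = 1e-4
        return GPRFit(
            beta=np.asarray(beta, dtype=float),
            alpha=-0.1,
            covariance=cov,
            loglik=0.0,
            converged=True,
            n_obs=10,
            iterations=1,
            labels=[f"x{i}" for i in range(k)],
        )

    def test_null_coefficient_row(self):
        rep = coefficient_report(self._dummy_fit([0.0], [0.1]))
        row = rep.iloc[0]
        assert row["irr"] == pytest.approx(1.0)
        assert row["wald_chi2"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)
        assert row["irr_low"] == pytest.approx(np.exp(-0.196), abs=1e-6)
        assert row["irr_high"] == pytest.approx(np.exp(0.196), abs=1e-6)

    @pytest.mark.parametrize("beta, irr", [(0.36, 1.43), (-0.34, 0.71), (0.33, 1.39)])
    def test_irr_is_exp_of_estimate(self, beta, irr):
        rep = coefficient_report(self._dummy_fit([beta], [0.05]))
        assert round(float(rep.iloc[0]["irr"]), 2) == irr

    def test_columns_recomputable_from_estimate_and_se(self, rng):
        y = gp_sample(GPParams(0.8, -0.2), 1500, seed=4)
        X = np.column_stack([np.ones(y.size), rng.binomial(1, 0.5, y.size)])
        fit = fit_gpr(X, y, labels=["Intercept", "exposed"])
        rep = coefficient_report(fit)
        b, s = rep["estimate"], rep["se"]
        assert np.allclose(rep["irr"], np.exp(b))
        assert np.allclose(rep["irr_low"], np.exp(b - 1.96 * s))
        assert np.allclose(rep["irr_high"], np.exp(b + 1.96 * s))
        assert np.allclose(rep["wald_chi2"], (b / s) ** 2)
        # CI straddles 1 exactly when the Wald p exceeds ~0.05
        straddles = (rep["irr_low"] < 1) & (1 < rep["irr_high"])
        assert straddles.tolist() == (rep["p_value"] > 0.0500).tolist()

    def test_reference_rows_marked(self, toy_families, toy_design):
        X, labels, y = build_design_matrix(toy_families, toy_design)
        fit = self._dummy_fit([0.1] * len(labels), [0.1] * len(labels))
        rep = coefficient_report(fit, labels, spec=toy_design)
        refs = rep[rep["reference"]]
        assert set(refs["term"]) == {"residence[rural]", "wealth_index[highest]"}
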