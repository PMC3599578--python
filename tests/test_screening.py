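import numpy as np
import pandas as pd
import pytest

from gpcount import descriptive_table, pearson_chi2, screen_predictors, select_predictors
from gpcount.exceptions import DataError
from gpcount.screening import bin_counts

# Reference bivariate screening p-values (religion is the only
# non-significant predictor).
REFERENCE_SCREEN = pd.DataFrame(
    {
        "predictor": [
            "residence",
            "mother_education",
            "father_education",
            "father_occupation",
            "wealth_index",
            "water_source",
            "toilet_facility",
            "religion",
            "media_access",
            "children_ever_born",
            "children_died",
        ],
        "p_value": [1e-4] * 7 + [0.925, 1e-4, 1e-4, 1e-4],
    }
)


class TestPearsonChi2:
    def test_hand_computed_two_by_two(self):
        # cells (10,20 / 20,10): every expected cell is 15, chi2 = 4*25/15
        x = ["a"] * 30 + ["b"] * 30
        y = ["u"] * 10 + ["v"] * 20 + ["u"] * 20 + ["v"] * 10
        chi2, df, p = pearson_chi2(x, y)
        assert chi2 == pytest.approx(20 / 3, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_perfect_independence(self):
        x = ["a", "a", "b", "b"] * 5
        y = ["u", "v", "u", "v"] * 5
        chi2, df, p = pearson_chi2(x, y)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_identical_rows_three_by_two(self):
        x = np.repeat(["r1", "r2", "r3"], 10)
        y = np.tile(["c1"] * 5 + ["c2"] * 5, 3)
        chi2, df, _ = pearson_chi2(x, y)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_symmetric_under_swap(self, rng):
        x = rng.choice(["a", "b", "c"], 200)
        y = rng.choice(["u", "v"], 200)
        assert pearson_chi2(x, y)[0] == pytest.approx(pearson_chi2(y, x)[0])

    def test_invariant_under_relabeling(self, rng):
        x = rng.choice(["a", "b"], 300)
        y = rng.choice(["u", "v", "w"], 300)
        relabel = {"u": "z1", "v": "z2", "w": "z3"}
        y2 = np.vectorize(relabel.get)(y)
        assert pearson_chi2(x, y)[0] == pytest.approx(pearson_chi2(x, y2)[0])

    def test_degenerate_table_rejected(self):
        with pytest.raises(DataError):
            pearson_chi2(["a"] * 10, ["u", "v"] * 5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            pearson_chi2(["a", "b"], ["u"])

    def test_type_i_error_near_level(self, rng):
        """Independent categorical pairs with comfortable expected cell
        counts reject at ~5%."""
        reject = 0
        reps = 400
        for _ in range(reps):
            x = rng.choice(["a", "b"], 300)
            y = rng.choice(["u", "v"], 300)
            reject += pearson_chi2(x, y)[2] < 0.05
        assert reject / reps == pytest.approx(0.05, abs=0.03)


class TestDescriptives:
    def test_counts_and_percentages(self, toy_design):
        df = pd.DataFrame(
            {
                "residence": ["urban"] * 4 + ["rural"] * 6,
                "wealth_index": ["highest"] * 10,
                "children_ever_born": [2, 3, 3] + [2] * 7,
            }
        )
        table = descriptive_table(df, toy_design)
        urban = table[(table.predictor == "residence") & (table.level == "urban")]
        assert int(urban.n.iloc[0]) == 4
        assert float(urban.pct.iloc[0]) == pytest.approx(40.0)
        lowest = table[(table.predictor == "wealth_index") & (table.level == "lowest")]
        assert int(lowest.n.iloc[0]) == 0
        assert float(lowest.pct.iloc[0]) == pytest.approx(0.0)
        cont = table[table.predictor == "children_ever_born"]
        assert float(cont["mean"].iloc[0]) == pytest.approx(2.2)

    def test_continuous_mean_small_sample(self, toy_design):
        df = pd.DataFrame(
            {
                "residence": ["rural"] * 3,
                "wealth_index": ["highest"] * 3,
                "children_ever_born": [2, 3, 3],
            }
        )
        table = descriptive_table(df, toy_design)
        cont = table[table.predictor == "children_ever_born"]
        assert float(cont["mean"].iloc[0]) == pytest.approx(8 / 3, abs=1e-9)

    def test_empty_input_rejected(self, toy_design):
        with pytest.raises(DataError):
            descriptive_table(pd.DataFrame(), toy_design)


class TestSelection:
    def test_reference_screen_drops_only_religion(self):
        kept = select_predictors(REFERENCE_SCREEN, level=0.05)
        assert "religion" not in kept
        assert len(kept) == 10

    def test_all_nonsignificant_gives_empty_list(self):
        res = pd.DataFrame({"predictor": ["a", "b"], "p_value": [0.5, 0.5]})
        assert select_predictors(res) == []

    def test_strict_inequality_at_boundary(self):
        res = pd.DataFrame({"predictor": ["a", "b"], "p_value": [0.049, 0.051]})
        assert select_predictors(res, level=0.05) == ["a"]


class TestScreenPredictors:
    def test_binning_caps_counts(self):
        assert bin_counts([0, 1, 2, 5], cap=2).tolist() == ["0", "1", "2+", "2+"]
        assert bin_counts([0, 3], cap=1).tolist() == ["0", "1+"]

    def test_detects_a_real_association(self, toy_design, rng):
        n = 2000
        residence = rng.choice(["urban", "rural"], n)
        lam = np.where(residence == "urban", 0.3, 0.9)
        df = pd.DataFrame(
            {
                "residence": residence,
                "wealth_index": rng.choice(
                    ["lowest", "second", "middle", "fourth", "highest"], n
                ),
                "children_ever_born": rng.integers(1, 6, n),
                "n_malnourished": rng.poisson(lam),
            }
        )
        table = screen_predictors(df, toy_design)
        res = table.set_index("predictor")
        assert bool(res.loc["residence", "selected"])
        assert res.loc["residence", "p_value"] < 1e-6
        assert res.loc["residence", "p_value"] < res.loc["wealth_index", "p_value"]
        assert (table["df"] > 0).all()
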