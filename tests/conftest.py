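import numpy as np
import pandas as pd
import pytest

from gpcount import Categorical, DesignSpec, GPParams


@pytest.fixture
def study_params() -> GPParams:
    """The GP parameters implied by the reference study moments."""
    return GPParams(mu=0.626, alpha=-0.3025)


@pytest.fixture
def toy_design() -> DesignSpec:
    return DesignSpec(
        categorical=(
            Categorical("residence", ("urban", "rural"), "rural"),
            Categorical(
                "wealth_index",
                ("lowest", "second", "middle", "fourth", "highest"),
                "highest",
            ),
        ),
        continuous=("children_ever_born",),
    )


@pytest.fixture
def toy_families() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [f"F{i}" for i in range(6)],
            "residence": ["urban", "rural", "rural", "urban", "rural", "rural"],
            "wealth_index": ["lowest", "second", "middle", "fourth", "highest", "highest"],
            "children_ever_born": [2, 3, 1, 4, 2, 5],
            "n_malnourished": [1, 0, 0, 2, 0, 1],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130108)
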