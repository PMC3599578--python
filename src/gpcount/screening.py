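"""Descriptive summaries and bivariate chi-square screening.

Candidate predictors enter the multivariable GP regression only if they
show a bivariate association with the outcome count.  Screening is the
classical Pearson chi-square test of independence on the cross-tabulation
of the (binned) family count against each predictor, with strict
``p < level`` selection and no continuity correction or multiplicity
adjustment.

Counts are binned 0 / 1 / 2+ by default to avoid sparse cells, and the
two integer-valued predictors (children ever born, children died) are
binned with configurable caps (4+ and 1+ by default); both binnings are
reconstructions exposed as knobs rather than fixed facts about the
source survey.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .exceptions import DataError
from .regression import DesignSpec

__all__ = [
    "descriptive_table",
    "pearson_chi2",
    "bin_counts",
    "screen_predictors",
    "select_predictors",
]

DEFAULT_CONTINUOUS_CAPS = {"children_ever_born": 4, "children_died": 1}


def descriptive_table(records: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Level counts and percentages per categorical predictor; means for
    continuous ones.  Percentages are of the non-missing records; levels
    absent from the data are reported with count 0."""
    if records.empty:
        raise DataError("cannot summarize an empty record collection")
    rows = []
    for cat in spec.categorical:
        if cat.name not in records.columns:
            raise DataError(f"records are missing predictor {cat.name!r}")
        obs = records[cat.name].dropna().astype(str)
        denom = len(obs)
        vc = obs.value_counts()
        for level in cat.levels:
            n = int(vc.get(level, 0))
            rows.append(
                {
                    "predictor": cat.name,
                    "level": level,
                    "n": n,
                    "pct": 100.0 * n / denom if denom else float("nan"),
                    "mean": float("nan"),
                }
            )
    for name in spec.continuous:
        if name not in records.columns:
            raise DataError(f"records are missing predictor {name!r}")
        obs = records[name].dropna()
        rows.append(
            {
                "predictor": name,
                "level": "",
                "n": int(len(obs)),
                "pct": float("nan"),
                "mean": float(obs.mean()),
            }
        )
    return pd.DataFrame(rows)


def pearson_chi2(outcome_categories, predictor_categories) -> tuple[float, int, float]:
    """Classical Pearson chi-square of independence.

    Returns ``(chi2, df, p)`` with ``df = (r-1)(c-1)`` after dropping
    empty rows/columns; no continuity correction.
    """
    a = pd.Series(outcome_categories).reset_index(drop=True)
    b = pd.Series(predictor_categories).reset_index(drop=True)
    if len(a) != len(b):
        raise DataError("category vectors must have equal length")
    table = pd.crosstab(a, b).to_numpy()
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DataError(
            f"degenerate contingency table of shape {table.shape}; "
            "need at least 2 rows and 2 columns"
        )
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def bin_counts(values, cap: int) -> pd.Series:
    """Integer values binned as '0', '1', ..., '{cap}+'."""
    v = pd.Series(values).astype(float)
    capped = np.minimum(v, cap)
    return capped.map(lambda x: f"{int(x)}+" if x >= cap else f"{int(x)}")


def screen_predictors(
    records: pd.DataFrame,
    spec: DesignSpec,
    outcome: str = "n_malnourished",
    level: float = 0.05,
    outcome_cap: int = 2,
    continuous_caps: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Bivariate chi-square screening of every predictor in the design.

    Returns one row per predictor: chi2, df, p_value, selected.
    """
    caps = dict(DEFAULT_CONTINUOUS_CAPS)
    caps.update(continuous_caps or {})
    if outcome not in records.columns:
        raise DataError(f"records are missing outcome column {outcome!r}")
    rows = []
    for cat in spec.categorical:
        sub = records[[outcome, cat.name]].dropna()
        chi2, df, p = pearson_chi2(
            bin_counts(sub[outcome], outcome_cap), sub[cat.name].astype(str)
        )
        rows.append(
            {"predictor": cat.name, "chi2": chi2, "df": df, "p_value": p,
             "selected": p < level}
        )
    for name in spec.continuous:
        sub = records[[outcome, name]].dropna()
        chi2, df, p = pearson_chi2(
            bin_counts(sub[outcome], outcome_cap),
            bin_counts(sub[name], caps.get(name, 4)),
        )
        rows.append(
            {"predictor": name, "chi2": chi2, "df": df, "p_value": p,
             "selected": p < level}
        )
    return pd.DataFrame(rows)


def select_predictors(results: pd.DataFrame, level: float = 0.05) -> list[str]:
    """Predictors with strictly ``p < level``, preserving input order."""
    return [
        str(r.predictor)
        for r in results.itertuples()
        if float(r.p_value) < level
    ]
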