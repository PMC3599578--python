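"""Reference study conditions: BDHS-2007-like covariate marginals and effects.

These constants describe the published aggregate features of the 2007
Bangladesh Demographic and Health Survey analysis that this package
emulates: covariate category frequencies, multivariable GP regression
coefficients (log incidence-rate scale, reference levels at 0), the
under-dispersion level, and the headline aggregates (mean count 0.626
per family, 16.9% child-level prevalence).  The raw survey is
access-restricted, so these marginals parametrize the synthetic-data
generator rather than re-deriving anything from microdata.

Printed percentage columns sum to 99.8-100.1 because of rounding; they
are renormalized here to exact probability vectors.
"""

from __future__ import annotations

from .regression import Categorical, DesignSpec

__all__ = [
    "TABLE_MARGINALS",
    "TRUE_BETA",
    "TRUE_ALPHA",
    "MEAN_COUNT",
    "CHILD_PREVALENCE",
    "EVER_BORN_MEAN",
    "DIED_MEAN",
    "covariate_design",
    "model_design",
]

#: Published sample mean / variance of the per-family count.
MEAN_COUNT = 0.626
COUNT_VARIANCE = 0.369
#: Published fraction of under-five children who are malnourished.
CHILD_PREVALENCE = 0.169
#: Published mean number of children ever born to a woman.
EVER_BORN_MEAN = 2.67
#: Published mean number of children died in a family.
DIED_MEAN = 0.24
#: Under-dispersion level used for simulation defaults.
TRUE_ALPHA = -0.30

_RAW_PCT = {
    "residence": {"urban": 35.70, "rural": 64.30},
    "mother_education": {
        "none": 25.50, "1-5y": 30.70, "6-10y": 35.10, "11+y": 8.60,
    },
    "father_education": {
        "none": 32.20, "1-5y": 27.80, "6-10y": 26.50, "11+y": 13.30,
    },
    "father_occupation": {
        "farmer": 25.53, "worker": 45.75, "professional": 4.59, "business": 24.12,
    },
    "toilet_facility": {"yes": 74.00, "no": 26.00},
    "water_source": {"piped": 6.70, "tubewell": 80.60, "other": 12.70},
    "religion": {"islam": 90.81, "other": 9.19},
    "media_access": {"yes": 29.10, "no": 70.10},
    "wealth_index": {
        "lowest": 19.00, "second": 20.20, "middle": 18.80,
        "fourth": 19.00, "highest": 23.00,
    },
}

#: Per-predictor level probabilities (each renormalized to sum to 1).
TABLE_MARGINALS: dict[str, dict[str, float]] = {
    pred: {lv: pct / sum(lvls.values()) for lv, pct in lvls.items()}
    for pred, lvls in _RAW_PCT.items()
}

_REFERENCES = {
    "residence": "rural",
    "mother_education": "11+y",
    "father_education": "11+y",
    "father_occupation": "business",
    "wealth_index": "highest",
    "water_source": "other",
    "toilet_facility": "yes",
    "religion": "other",
    "media_access": "yes",
}

#: Multivariable GP regression coefficients (log-IRR scale); reference
#: levels are implicitly 0.  Religion carries no effect (it is screened
#: out of the multivariable model).
TRUE_BETA: dict[str, float] = {
    "residence[urban]": 0.06,
    "mother_education[none]": 0.33,
    "mother_education[1-5y]": 0.32,
    "mother_education[6-10y]": 0.22,
    "father_education[none]": 0.29,
    "father_education[1-5y]": 0.26,
    "father_education[6-10y]": 0.20,
    "father_occupation[farmer]": 0.39,
    "father_occupation[worker]": 0.32,
    "father_occupation[professional]": 0.11,
    "wealth_index[lowest]": 0.50,
    "wealth_index[second]": 0.41,
    "wealth_index[middle]": 0.33,
    "wealth_index[fourth]": 0.22,
    "water_source[piped]": -0.24,
    "water_source[tubewell]": -0.34,
    "toilet_facility[no]": 0.36,
    "media_access[no]": 0.08,
    "children_ever_born": 0.05,
    "children_died": -0.03,
}

CONTINUOUS = ("children_ever_born", "children_died")


def _categorical(name: str) -> Categorical:
    return Categorical(
        name=name,
        levels=tuple(TABLE_MARGINALS[name].keys()),
        reference=_REFERENCES[name],
    )


def covariate_design() -> DesignSpec:
    """All candidate predictors (including religion) — the screening set."""
    return DesignSpec(
        categorical=tuple(_categorical(n) for n in _RAW_PCT),
        continuous=CONTINUOUS,
    )


def model_design() -> DesignSpec:
    """The multivariable model design: every predictor except religion."""
    return DesignSpec(
        categorical=tuple(_categorical(n) for n in _RAW_PCT if n != "religion"),
        continuous=CONTINUOUS,
    )
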