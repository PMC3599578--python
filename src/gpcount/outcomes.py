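"""Construction of the outcome: malnourished under-five children per family.

A child is classified as malnourished (wasted) when the weight-for-height
Z-score (WHZ) lies strictly below -2 SD of the reference-population
median; the family-level outcome is the number of such children among a
family's under-five children with anthropometry.  Children without
measurements, or outside 0-59 months, are excluded before counting (with
a logged count).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "WHZ_CUTOFF",
    "classify_malnourished",
    "family_counts",
    "prevalence",
    "read_children",
    "write_families",
]

logger = logging.getLogger(__name__)

WHZ_CUTOFF = -2.0

CHILD_COLUMNS = ["child_id", "family_id", "whz", "age_months"]


def classify_malnourished(whz: float) -> int:
    """1 if the Z-score is strictly below -2 SD, else 0."""
    if whz is None or not np.isfinite(whz):
        raise DataError(f"whz must be a finite number, got {whz!r}")
    return int(whz < WHZ_CUTOFF)


def _included(children: pd.DataFrame) -> pd.DataFrame:
    for col in CHILD_COLUMNS:
        if col not in children.columns:
            raise DataError(f"child records are missing field {col!r}")
    if children["child_id"].duplicated().any():
        dup = children.loc[children["child_id"].duplicated(), "child_id"].iloc[0]
        raise DataError(f"duplicate child id {dup!r}")
    df = children
    if "measured" in df.columns:
        df = df[df["measured"].astype(bool)]
    whz = pd.to_numeric(df["whz"], errors="coerce")
    df = df[np.isfinite(whz.to_numpy(dtype=float))] if len(df) else df
    df = df[(df["age_months"] >= 0) & (df["age_months"] <= 59)]
    excluded = len(children) - len(df)
    if excluded:
        logger.info(
            "excluded %d of %d children (unmeasured or outside 0-59 months)",
            excluded,
            len(children),
        )
    return df


def family_counts(children: pd.DataFrame) -> pd.DataFrame:
    """One row per family: the number of its malnourished children.

    Families whose measured children are all well-nourished get count 0.
    Invariant to input row order; the counts sum to the number of
    malnourished children.
    """
    df = _included(children)
    if df.empty:
        raise DataError("no measured children in 0-59 months remain")
    flagged = (df["whz"] < WHZ_CUTOFF).astype(int)
    out = (
        flagged.groupby(df["family_id"])
        .sum()
        .rename("n_malnourished")
        .reset_index()
        .sort_values("family_id", kind="stable")
        .reset_index(drop=True)
    )
    return out


def prevalence(children: pd.DataFrame) -> float:
    """Fraction of measured under-five children who are malnourished."""
    df = _included(children)
    if df.empty:
        raise DataError("no measured children to compute prevalence from")
    return float((df["whz"] < WHZ_CUTOFF).mean())


def read_children(path: str | Path) -> pd.DataFrame:
    """Read child-level delimited text (header: child_id, family_id, whz,
    age_months[, measured])."""
    df = pd.read_csv(path)
    missing = [c for c in CHILD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing child columns {missing}")
    return df


def write_families(path: str | Path, families: pd.DataFrame) -> None:
    families.to_csv(path, index=False)
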