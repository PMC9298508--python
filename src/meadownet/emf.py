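"""Ecosystem-multifunctionality (EMF) index.

The EMF of a sample is the mean of the Z-scores of seven support/regulation
variables: total vegetation coverage, dry weight, wet weight, NH4-N, NO3-N,
SOC and TN. Z-scores are computed jointly over all samples (sample SD,
n-1 denominator), so group EMF means are directly comparable and the grand
mean is exactly zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the seven ecosystem-function variables entering the index
FUNCTION_COLUMNS = (
    "total_coverage", "dry_weight", "wet_weight", "NH4N", "NO3N", "SOC", "TN",
)


def function_matrix(env: pd.DataFrame, columns=FUNCTION_COLUMNS,
                    impute: bool = False) -> pd.DataFrame:
    """Select the function columns from an environment table.

    Missing values are refused unless ``impute`` is set, in which case they
    are replaced by the column mean (logged).
    """
    missing = set(columns) - set(env.columns)
    if missing:
        raise ValueError(f"environment table missing function columns: {sorted(missing)}")
    m = env.loc[:, list(columns)].astype(float)
    if m.isna().any().any():
        if not impute:
            raise ValueError("missing values in function matrix (set impute=True to fill)")
        n_missing = int(m.isna().sum().sum())
        logger.warning("imputing %d missing function values with column means", n_missing)
        m = m.fillna(m.mean())
    return m


def zscore_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample SD 1, over all samples jointly."""
    sd = m.std(ddof=1)
    zero = sd == 0
    if zero.any():
        raise ValueError(f"zero-SD function column(s): {list(m.columns[zero])}")
    return (m - m.mean()) / sd


def emf_scores(m: pd.DataFrame) -> pd.Series:
    """Per-sample EMF: mean of the function Z-scores; grand mean is 0."""
    scores = zscore_columns(m).mean(axis=1)
    scores.name = "emf"
    return scores


def group_emf(scores: pd.Series, frame: pd.DataFrame,
              by=("disturbance", "surface")) -> pd.DataFrame:
    """Mean, SD and n of EMF per metadata group, ordered by group label."""
    by = [by] if isinstance(by, str) else list(by)
    meta = frame.loc[scores.index, by]
    joined = pd.concat([meta, scores], axis=1)
    out = joined.groupby(by)["emf"].agg(mean="mean", sd="std", n="size").reset_index()
    if (out["n"] == 0).any():
        raise ValueError("empty EMF group")
    return out.sort_values(by).reset_index(drop=True)
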