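"""Alpha diversity (Chao1, observed OTUs, Shannon, Simpson) and
Bray-Curtis community dissimilarity / similarity."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import CountTable, ValidationError


def observed_otus(counts) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(np.asarray(counts)))


def chao1(counts) -> float:
    """Chao1 richness estimator.

    Classic form S_obs + F1^2 / (2 F2) when doubletons exist; the
    bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0.
    Equals S_obs when there are no singletons.
    """
    c = np.asarray(counts)
    s_obs = np.count_nonzero(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts, base: float = np.e) -> float:
    """Shannon entropy -sum p ln p (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("zero-sum count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson(counts, gini: bool = True) -> float:
    """Gini-Simpson index 1 - sum p^2 (or raw dominance D with gini=False)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("zero-sum count vector")
    d = float(((c / total) ** 2).sum())
    return 1.0 - d if gini else d


def alpha_diversity(table: CountTable, shannon_base: float = np.e) -> pd.DataFrame:
    """Per-sample alpha diversity table with the four standard metrics."""
    records = []
    for sid, row in table.data.iterrows():
        c = row.to_numpy()
        records.append({
            "sample_id": sid,
            "observed": observed_otus(c),
            "chao1": chao1(c),
            "shannon": shannon(c, base=shannon_base),
            "simpson": simpson(c),
        })
    return pd.DataFrame(records).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(u, v) = sum |u - v| / sum (u + v)."""
    if table.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if (table.data.sum(axis=1) == 0).any():
        raise ValidationError("zero-sum sample")
    condensed = pdist(table.data.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def community_similarity(dm: DistanceMatrix) -> pd.DataFrame:
    """Similarity = 1 - dissimilarity, diagonal 1; requires entries in [0, 1]."""
    data = dm.data
    if data.min() < 0 or data.max() > 1:
        raise ValidationError("dissimilarities must lie in [0, 1]")
    return pd.DataFrame(1.0 - data, index=list(dm.ids), columns=list(dm.ids))


def within_group_similarity(
    dm: DistanceMatrix, frame: pd.DataFrame, by: list[str] | str = ("disturbance", "surface")
) -> pd.DataFrame:
    """Mean +/- SD of pairwise similarity within each metadata group.

    The group summary of community similarity; reported as the mean over
    all within-group sample pairs.
    """
    by = [by] if isinstance(by, str) else list(by)
    sim = community_similarity(dm)
    rows = []
    for key, members in frame.loc[list(dm.ids)].groupby(by):
        ids = list(members.index)
        if len(ids) < 2:
            continue
        block = sim.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), 1)
        vals = block[iu]
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(by, key)) | {
            "mean_similarity": vals.mean(),
            "sd_similarity": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n_pairs": len(vals),
        })
    return pd.DataFrame(rows)
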