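"""Inferential layer: enrichment ratios, ANOVA, Mann-Whitney U, PERMANOVA,
Mantel test, multiple regression on distance matrices (MRM) and simple
least-squares regression.

All permutation tests use the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations), so p is
never smaller than 1/(n_permutations + 1). Each test also supports
``permutations="exhaustive"``, which enumerates every distinct label
arrangement (PERMANOVA) or sample permutation (Mantel/MRM) and reports the
exact permutation p over that enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from ._util import multiset_permutations
from .tables import CountTable, relative_abundance

logger = logging.getLogger(__name__)


@dataclass
class PermTestResult:
    statistic: float
    p: float
    n_permutations: int
    seed: int | None = None
    r2: float | None = None
    method: str = ""


@dataclass
class MrmResult:
    coefficients: pd.Series  # intercept first
    r2: float
    p_values: pd.Series
    n_permutations: int
    seed: int | None = None
    collinear: bool = False


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float


@dataclass
class EnrichmentReport:
    group: str
    n_otus_tested: int
    n_enriched: int
    alpha: float

    @property
    def ratio(self) -> float:
        return self.n_enriched / self.n_otus_tested if self.n_otus_tested else float("nan")


# ---------------------------------------------------------------------------
# Classic univariate tests
# ---------------------------------------------------------------------------

def oneway_anova(values, labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U with rank-sum U and tie correction.

    Exact p by enumeration for small samples (n_x + n_y <= 12, no ties);
    normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def linear_regression(x, y) -> RegressionResult:
    """Least-squares fit y = a + b x with R^2 and the slope's F-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Enrichment ratios
# ---------------------------------------------------------------------------

def enrichment_ratio(
    table: CountTable,
    frame: pd.DataFrame,
    focal: dict[str, str],
    control: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> EnrichmentReport:
    """Fraction of OTUs significantly enriched in a focal group vs control.

    Per OTU a one-way ANOVA on relative abundance between the focal and
    control samples; enriched means p < alpha AND a higher focal mean
    (significance alone is direction-blind). OTUs absent from both groups
    are excluded from the denominator. ``focal`` and ``control`` map
    metadata columns to required values; control defaults to the natural
    meadow, ``{"disturbance": "C"}``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    control = control if control is not None else {"disturbance": "C"}

    def select(cond):
        mask = pd.Series(True, index=frame.index)
        for col, val in cond.items():
            mask &= frame[col] == val
        ids = [s for s in table.sample_ids if s in set(frame.index[mask])]
        if not ids:
            raise ValueError(f"empty group for condition {cond}")
        return ids

    focal_ids, control_ids = select(focal), select(control)
    rel = relative_abundance(table)
    f_block = rel.loc[focal_ids].to_numpy()
    c_block = rel.loc[control_ids].to_numpy()
    present = (f_block.sum(axis=0) + c_block.sum(axis=0)) > 0
    n_skipped = int((~present).sum())
    if n_skipped:
        logger.info("enrichment_ratio: excluding %d OTU(s) absent from both groups",
                    n_skipped)
    n_enriched = 0
    n_tested = 0
    for j in np.where(present)[0]:
        fx, cx = f_block[:, j], c_block[:, j]
        n_tested += 1
        if np.ptp(fx) == 0 and np.ptp(cx) == 0 and fx.mean() == cx.mean():
            continue  # identical constant abundance: not enriched
        _, p = stats.f_oneway(fx, cx)
        if p < alpha and fx.mean() > cx.mean():
            n_enriched += 1
    label = ",".join(f"{k}={v}" for k, v in focal.items())
    return EnrichmentReport(group=label, n_otus_tested=n_tested,
                            n_enriched=n_enriched, alpha=alpha)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, label_codes: np.ndarray, n_groups: int):
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = label_codes == g
        n_g = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_between = ss_total - ss_within
    a = n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    if ss_within == 0:
        f = math.inf if ss_between > 0 else math.nan
    return f, ss_between / ss_total


def permanova(dm: DistanceMatrix, grouping, permutations=999, seed=None,
              strata=None) -> PermTestResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum of squared distances / n over all pairs; SS_within the
    analogous per-group sums; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
    p by unrestricted label permutation with the add-one convention, or the
    exact enumeration p with ``permutations="exhaustive"``. ``strata``
    optionally restricts permutations to shuffle within blocks (a vector of
    block labels per sample).
    """
    labels = np.asarray(grouping)
    n = len(labels)
    if n != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need >= 2 groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("every group needs >= 2 samples")
    d2 = dm.data ** 2
    f_obs, r2 = _permanova_f(d2, codes, a)

    if permutations == "exhaustive":
        count = 0
        total = 0
        for arrangement in multiset_permutations(list(codes)):
            f_perm, _ = _permanova_f(d2, np.asarray(arrangement), a)
            count += f_perm >= f_obs
            total += 1
        return PermTestResult(statistic=float(f_obs), p=count / total,
                              n_permutations=total, seed=None, r2=float(r2),
                              method="permanova-exhaustive")

    rng = np.random.default_rng(seed)
    perms = np.empty((permutations, n), dtype=np.int64)
    if strata is None:
        for i in range(permutations):
            perms[i] = rng.permutation(codes)
    else:
        strata = np.asarray(strata)
        for i in range(permutations):
            perm = codes.copy()
            for s in np.unique(strata):
                idx = np.where(strata == s)[0]
                perm[idx] = perm[rng.permutation(idx)]
            perms[i] = perm
    # vectorized within-group sums: for each group an indicator matrix U,
    # the group pair-sum is diag(U D2 U^T)
    n_per = np.bincount(codes, minlength=a).astype(float)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(permutations)
    for g in range(a):
        u = (perms == g).astype(float)
        ss_within += ((u @ d2) * u).sum(axis=1) / (2.0 * n_per[g])
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between / (a - 1)) / (ss_within / (n - a))
    f_perm[ss_within == 0] = math.inf
    exceed = int((f_perm >= f_obs).sum())
    p = (1 + exceed) / (1 + permutations)
    return PermTestResult(statistic=float(f_obs), p=p, n_permutations=permutations,
                          seed=seed, r2=float(r2), method="permanova")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _rank_matrix(d: np.ndarray) -> np.ndarray:
    """Rank-transform the upper-triangle entries, mirrored back to a matrix."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(d[iu])
    out = np.zeros_like(d, dtype=float)
    out[iu] = ranks
    out.T[iu] = ranks
    return out


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, permutations=999, seed=None,
           method: str = "pearson", alternative: str = "two-sided") -> PermTestResult:
    """Mantel correlation between two distance matrices.

    r is the (Pearson by default, Spearman by flag) correlation of the
    upper-triangle entries; p comes from jointly permuting the rows and
    columns of the first matrix.
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices cover different samples")
        d2 = d2.filter(d1.ids)
    a = d1.data.astype(float)
    b = d2.data.astype(float)
    if method == "spearman":
        a, b = _rank_matrix(a), _rank_matrix(b)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    m = len(iu[0])
    mu_a, mu_b = a[iu].mean(), b[iu].mean()
    sd_a, sd_b = a[iu].std(), b[iu].std()
    if sd_a == 0 or sd_b == 0:
        raise ValueError("a distance matrix is constant")
    # center both matrices on their off-diagonal means and zero the diagonal:
    # the permuted-r numerator is then a plain elementwise product sum
    bc = b - mu_b
    np.fill_diagonal(bc, 0.0)
    ac = a - mu_a
    np.fill_diagonal(ac, 0.0)
    # same expression as the permuted statistics, so ties are exact
    r_obs = (ac * bc).sum() / (2.0 * m * sd_a * sd_b)

    def stat(r):
        if alternative == "two-sided":
            return abs(r)
        if alternative == "greater":
            return r
        if alternative == "less":
            return -r
        raise ValueError(f"unknown alternative {alternative!r}")

    if permutations == "exhaustive":
        count = total = 0
        for perm in iter_permutations(range(n)):
            idx = np.asarray(perm)
            ap = ac[np.ix_(idx, idx)]
            r_p = (ap * bc).sum() / (2.0 * m * sd_a * sd_b)
            count += stat(r_p) >= stat(r_obs)
            total += 1
        return PermTestResult(statistic=float(r_obs), p=count / total,
                              n_permutations=total, seed=None,
                              method=f"mantel-{method}-exhaustive")

    rng = np.random.default_rng(seed)
    idx = np.vstack([rng.permutation(n) for _ in range(permutations)])
    ap = ac[idx[:, :, None], idx[:, None, :]]  # (P, n, n)
    r_perm = np.einsum("pij,ij->p", ap, bc) / (2.0 * m * sd_a * sd_b)
    exceed = int((stat(r_perm) >= stat(r_obs)).sum()) if alternative != "two-sided" \
        else int((np.abs(r_perm) >= abs(r_obs)).sum())
    p = (1 + exceed) / (1 + permutations)
    return PermTestResult(statistic=float(r_obs), p=p, n_permutations=permutations,
                          seed=seed, method=f"mantel-{method}")


# ---------------------------------------------------------------------------
# MRM
# ---------------------------------------------------------------------------

def mrm(response: DistanceMatrix, predictors: list[DistanceMatrix],
        permutations=999, seed=None, names=None) -> MrmResult:
    """Multiple regression of a distance matrix on predictor matrices.

    OLS on the unfolded upper triangles with an intercept; per-coefficient
    p by jointly permuting the rows/columns of the response matrix and
    refitting (two-sided on |coefficient|).
    """
    if not predictors:
        raise ValueError("need >= 1 predictor matrix")
    ids = list(response.ids)
    preds = []
    for d in predictors:
        if list(d.ids) != ids:
            if set(d.ids) != set(ids):
                raise ValueError("predictor covers different samples")
            d = d.filter(ids)
        preds.append(d.data.astype(float))
    y_mat = response.data.astype(float)
    n = y_mat.shape[0]
    iu = np.triu_indices(n, 1)
    x = np.column_stack([np.ones(len(iu[0]))] + [p[iu] for p in preds])
    names = list(names) if names is not None else [f"x{k+1}" for k in range(len(preds))]
    coef_names = ["intercept"] + names

    collinear = np.linalg.matrix_rank(x) < x.shape[1]
    if collinear:
        logger.warning("mrm: predictor matrices are collinear; "
                       "coefficients are a minimum-norm solution")
    pinv = np.linalg.pinv(x)
    y = y_mat[iu]
    beta = pinv @ y
    resid = y - x @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else float("nan")

    if permutations == "exhaustive":
        perm_iter = [np.asarray(p) for p in iter_permutations(range(n))]
        betas = np.vstack([pinv @ y_mat[np.ix_(p, p)][iu] for p in perm_iter])
        exceed = (np.abs(betas) >= np.abs(beta)).sum(axis=0)
        pvals = exceed / len(perm_iter)
        n_perm = len(perm_iter)
    else:
        rng = np.random.default_rng(seed)
        idx = np.vstack([rng.permutation(n) for _ in range(permutations)])
        yp = y_mat[idx[:, :, None], idx[:, None, :]][:, iu[0], iu[1]]  # (P, m)
        betas = yp @ pinv.T
        exceed = (np.abs(betas) >= np.abs(beta)).sum(axis=0)
        pvals = (1 + exceed) / (1 + permutations)
        n_perm = permutations
    return MrmResult(
        coefficients=pd.Series(beta, index=coef_names),
        r2=float(r2),
        p_values=pd.Series(pvals, index=coef_names),
        n_permutations=n_perm, seed=seed, collinear=bool(collinear),
    )
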