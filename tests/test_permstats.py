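import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from meadownet.permstats import (EnrichmentReport, enrichment_ratio,
                                 linear_regression, mann_whitney_u, mantel,
                                 mrm, oneway_anova, permanova)
from meadownet.tables import CountTable


def random_dm(rng, n):
    pts = rng.normal(size=(n, 4))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


class TestAnova:
    def test_separated_groups_large_f(self):
        values = [1.0, 1.1, 0.9, 5.0, 5.1, 4.9]
        labels = ["a"] * 3 + ["b"] * 3
        f, p = oneway_anova(values, labels)
        assert f > 100 and p < 1e-4

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, size=10)
        f, p_f = oneway_anova(np.concatenate([x, y]), ["a"] * 10 + ["b"] * 10)
        t, p_t = stats.ttest_ind(x, y)
        assert f == pytest.approx(t ** 2)
        assert p_f == pytest.approx(p_t)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1, 2, 3], ["a", "a", "b"])


class TestMannWhitney:
    def test_complete_separation_extreme_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)

    def test_identical_samples_p_near_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert p > 0.9

    def test_exact_p_matches_enumeration(self):
        # n_x = n_y = 4, no ties: enumerate all C(8,4) = 70 assignments
        x = np.array([1.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 4.0, 6.0, 7.0])
        u_obs, p_obs = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        n = 4
        us = []
        for idx in itertools.combinations(range(8), n):
            xi = pooled[list(idx)]
            yi = pooled[[k for k in range(8) if k not in idx]]
            ranks = stats.rankdata(np.concatenate([xi, yi]))
            u1 = ranks[:n].sum() - n * (n + 1) / 2
            us.append(u1)
        us = np.asarray(us)
        # two-sided exact p: distribution of U is symmetric about n^2/2
        dev = np.abs(us - n * n / 2)
        dev_obs = abs(u_obs - n * n / 2)
        p_exact = (dev >= dev_obs).mean()
        assert p_obs == pytest.approx(p_exact)


class TestPermanova:
    def test_exhaustive_separated_groups(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        res = permanova(dm, ["x"] * 3 + ["y"] * 3, permutations="exhaustive")
        assert res.p == pytest.approx(2 / 20)
        assert res.n_permutations == 20
        assert math.isinf(res.statistic)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(1)
        dm = random_dm(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, labels, permutations=99, seed=0)
        ref = skbio_permanova(dm, np.asarray(labels), permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_exhaustive_matches_direct_enumeration(self):
        rng = np.random.default_rng(2)
        dm = random_dm(rng, 6)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, labels, permutations="exhaustive")
        # independent enumeration over index subsets
        d2 = dm.data ** 2
        n = 6

        def pseudo_f(group_a):
            ss_total = d2.sum() / (2 * n)
            ss_w = 0.0
            for g in (group_a, [i for i in range(n) if i not in group_a]):
                sub = d2[np.ix_(g, g)]
                ss_w += sub.sum() / (2 * len(g))
            ss_b = ss_total - ss_w
            return (ss_b / 1) / (ss_w / 4)

        f_obs = pseudo_f([0, 1, 2])
        fs = [pseudo_f(list(c)) for c in itertools.combinations(range(6), 3)]
        p_exact = np.mean([f >= f_obs for f in fs])
        assert res.statistic == pytest.approx(f_obs)
        assert res.p == pytest.approx(p_exact)

    def test_duplicating_structure_preserves_r2(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        pts[:4] += 2.0
        big = np.vstack([pts, pts])
        def dm_of(p):
            d = np.sqrt(((p[:, None] - p[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0)
            return DistanceMatrix(d, ids=[f"s{i}" for i in range(len(p))])
        labels = ["a"] * 4 + ["b"] * 4
        r2_small = permanova(dm_of(pts), labels, permutations=9, seed=0).r2
        r2_big = permanova(dm_of(big), labels * 2, permutations=9, seed=0).r2
        assert r2_big == pytest.approx(r2_small)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        dm = random_dm(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        ids = list(dm.ids)
        dm2 = dm.filter([ids[i] for i in perm])
        res1 = permanova(dm, labels, permutations=199, seed=5)
        res2 = permanova(dm2, labels[perm], permutations=199, seed=5)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            permanova(random_dm(rng, 5), ["a", "b", "b", "b", "b"],
                      permutations=9, seed=0)


class TestMantel:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(6)
        dm = random_dm(rng, 8)
        res = mantel(dm, dm, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_transform_r_one(self):
        rng = np.random.default_rng(7)
        dm = random_dm(rng, 8)
        d2 = DistanceMatrix(dm.data * 3.0 + 1.0 - np.diag(np.full(8, 1.0)),
                            ids=list(dm.ids))
        res = mantel(dm, d2, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(8)
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        mine = mantel(d1, d2, permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert mine.statistic == pytest.approx(r_ref)

    def test_spearman_statistic_matches_skbio(self):
        rng = np.random.default_rng(9)
        d1, d2 = random_dm(rng, 9), random_dm(rng, 9)
        mine = mantel(d1, d2, permutations=49, seed=0, method="spearman")
        r_ref, _, _ = skbio_mantel(d1, d2, method="spearman", permutations=0)
        assert mine.statistic == pytest.approx(r_ref)

    def test_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(10)
        d1, d2 = random_dm(rng, 4), random_dm(rng, 4)
        res = mantel(d1, d2, permutations="exhaustive")
        iu = np.triu_indices(4, 1)

        def r_of(perm):
            a = d1.data[np.ix_(perm, perm)][iu]
            b = d2.data[iu]
            return stats.pearsonr(a, b).statistic

        r_obs = r_of(list(range(4)))
        rs = [r_of(list(p)) for p in itertools.permutations(range(4))]
        p_exact = np.mean([abs(r) >= abs(r_obs) - 1e-12 for r in rs])
        assert res.statistic == pytest.approx(r_obs)
        assert res.p == pytest.approx(p_exact)
        assert res.n_permutations == 24

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(11)
        d1 = random_dm(rng, 5)
        d2 = DistanceMatrix(random_dm(rng, 5).data, ids=list("vwxyz"))
        with pytest.raises(ValueError):
            mantel(d1, d2, permutations=9, seed=0)


class TestMrm:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(12)
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        y = 2.0 * d1.data + 0.5 * d2.data
        resp = DistanceMatrix(y, ids=list(d1.ids))
        res = mrm(resp, [d1, d2], permutations=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-9)
        assert res.coefficients["x2"] == pytest.approx(0.5, abs=1e-9)
        assert res.coefficients["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_single_predictor_r2_is_squared_mantel_r(self):
        rng = np.random.default_rng(13)
        d1, d2 = random_dm(rng, 9), random_dm(rng, 9)
        res = mrm(d1, [d2], permutations=49, seed=0)
        r = mantel(d1, d2, permutations=49, seed=0).statistic
        assert res.r2 == pytest.approx(r ** 2)

    def test_collinear_predictors_flagged(self):
        rng = np.random.default_rng(14)
        d1 = random_dm(rng, 8)
        d2 = DistanceMatrix(d1.data * 2.0, ids=list(d1.ids))
        res = mrm(random_dm(rng, 8), [d1, d2], permutations=9, seed=0)
        assert res.collinear

    def test_p_floor_add_one_convention(self):
        rng = np.random.default_rng(15)
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        res = mrm(d1, [d2], permutations=99, seed=0)
        assert (res.p_values >= 1 / 100).all()


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_centering_x_shifts_intercept_only(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        a = linear_regression(x, y)
        b = linear_regression(x - x.mean(), y)
        assert a.slope == pytest.approx(b.slope)
        assert a.r2 == pytest.approx(b.r2)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1, 1, 1], [1, 2, 3])


class TestEnrichmentRatio:
    def frame(self, n_focal, n_control):
        return pd.DataFrame({
            "disturbance": ["P"] * n_focal + ["C"] * n_control,
            "surface": ["G"] * (n_focal + n_control),
            "block": ["b"] * (n_focal + n_control),
            "site": ["s"] * (n_focal + n_control),
        }, index=[f"s{i}" for i in range(n_focal + n_control)])

    def test_null_ratio_small(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(1, 200, size=(40, 60))
        table = CountTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(40)],
            columns=[f"o{j}" for j in range(60)]))
        rep = enrichment_ratio(table, self.frame(20, 20),
                               focal={"disturbance": "P"})
        assert rep.ratio < 0.08  # at most ~alpha/2 plus noise

    def test_all_zero_otu_excluded_from_denominator(self):
        counts = np.array([[10, 0, 1], [12, 0, 2], [11, 0, 2], [9, 0, 1]])
        table = CountTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(4)], columns=list("abc")))
        rep = enrichment_ratio(table, self.frame(2, 2),
                               focal={"disturbance": "P"})
        assert rep.n_otus_tested == 2

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(18)
        base = rng.integers(50, 150, size=60)
        focal = rng.poisson(base * np.where(np.arange(60) < 12, 4.0, 1.0),
                            size=(20, 60))
        control = rng.poisson(base, size=(20, 60))
        table = CountTable(pd.DataFrame(
            np.vstack([focal, control]),
            index=[f"s{i}" for i in range(40)],
            columns=[f"o{j}" for j in range(60)]))
        rep = enrichment_ratio(table, self.frame(20, 20),
                               focal={"disturbance": "P"})
        assert 0.15 <= rep.ratio <= 0.30

    def test_empty_group_rejected(self):
        table = CountTable(pd.DataFrame(
            [[1, 2]] * 4, index=[f"s{i}" for i in range(4)], columns=list("ab")))
        with pytest.raises(ValueError, match="empty group"):
            enrichment_ratio(table, self.frame(2, 2), focal={"disturbance": "PL"})

    def test_ratio_property(self):
        rep = EnrichmentReport(group="g", n_otus_tested=50, n_enriched=10, alpha=0.05)
        assert rep.ratio == pytest.approx(0.2)
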