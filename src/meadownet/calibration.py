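"""Validation harnesses: independent oracles, type-I calibration and
planted-structure recovery.

These routines exist so the statistical machinery can be checked against
brute-force references (exhaustive enumeration, BFS, triangle counting) and
against the ground truth planted by :mod:`meadownet.synthetic`. They are run
by the test suite and the acceptance script; none of them is used by the
analysis pipeline itself.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from . import network as conet
from .emf import emf_scores
from .permstats import (linear_regression, mann_whitney_u, mantel, mrm,
                        oneway_anova, permanova)
from .synthetic import (CommunityConfig, CorrelationBlock, EnrichmentSet,
                        generate_counts, planted_truth)
from .tables import CountTable


# ---------------------------------------------------------------------------
# Brute-force graph oracles
# ---------------------------------------------------------------------------

def brute_force_topology(g: nx.Graph) -> dict:
    """Clustering, path length, diameter and density by direct enumeration.

    Local clustering by triangle counting over neighbour pairs; distances
    by per-source breadth-first search; intended for small graphs only.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    e = g.number_of_edges()
    adj = {u: set(g.neighbors(u)) for u in nodes}

    cc = []
    for u in nodes:
        nb = list(adj[u])
        k = len(nb)
        if k < 2:
            cc.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if b in adj[a])
        cc.append(2.0 * links / (k * (k - 1)))

    total = pairs = 0
    diameter = 0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, dv in dist.items():
            if v != src:
                total += dv
                pairs += 1
                diameter = max(diameter, dv)
    return {
        "avg_clustering_coefficient": sum(cc) / n if n else float("nan"),
        "avg_path_length": total / pairs if pairs else float("nan"),
        "diameter": float(diameter) if pairs else float("nan"),
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else float("nan"),
    }


def topology_oracle_max_diff(n_graphs: int = 50, n_max: int = 20,
                             p_edge: float = 0.25, seed: int = 0) -> float:
    """Largest absolute disagreement between topology_summary and the
    brute-force oracle over random Erdos-Renyi graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_graphs):
        n = int(rng.integers(4, n_max + 1))
        g = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(2**31)))
        nx.set_edge_attributes(g, "+", "sign")
        nx.set_edge_attributes(g, 1.0, "rho")
        summ = conet.topology_summary(g).to_dict()
        ref = brute_force_topology(g)
        for key, val in ref.items():
            a, b = summ[key], val
            if np.isnan(a) and np.isnan(b):
                continue
            worst = max(worst, abs(a - b))
    return worst


def spearman_oracle_max_diff(n: int = 30, n_trials: int = 100, seed: int = 0) -> float:
    """Max |spearman rho - Pearson on average ranks| over random tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        counts = rng.integers(0, 50, size=(n, 6))
        counts[:, 0] += 1  # keep row sums positive
        table = CountTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n)],
            columns=[f"o{j}" for j in range(6)]), domain="bacteria")
        res = conet.spearman_all_pairs(table)
        rel = counts / counts.sum(axis=1, keepdims=True)
        ranked = np.apply_along_axis(stats.rankdata, 0, rel)
        pearson = np.corrcoef(ranked, rowvar=False)
        otus = [f"o{j}" for j in range(6)]
        for row in res.itertuples(index=False):
            i, j = otus.index(row.otu_i), otus.index(row.otu_j)
            worst = max(worst, abs(row.rho - pearson[i, j]))
    return worst


# ---------------------------------------------------------------------------
# Type-I error calibration
# ---------------------------------------------------------------------------

def _random_euclidean_dm(rng, n, dim=5) -> DistanceMatrix:
    pts = rng.normal(size=(n, dim))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


def type_i_error(test: str, n_sims: int = 500, n: int = 24, alpha: float = 0.05,
                 n_perm: int = 999, seed: int = 0) -> float:
    """Empirical rejection rate of a test under its null.

    ``test`` is one of permanova, mantel, mrm, anova, mannwhitney. Data are
    generated with no group structure / no association, so the rejection
    rate should approximate ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    for k in range(n_sims):
        s = int(rng.integers(2**31))
        if test == "permanova":
            dm = _random_euclidean_dm(rng, n)
            res = permanova(dm, labels, permutations=n_perm, seed=s)
            p = res.p
        elif test == "mantel":
            d1 = _random_euclidean_dm(rng, n)
            d2 = _random_euclidean_dm(rng, n)
            res = mantel(d1, d2, permutations=n_perm, seed=s)
            p = res.p
        elif test == "mrm":
            d1 = _random_euclidean_dm(rng, n)
            d2 = _random_euclidean_dm(rng, n)
            d3 = _random_euclidean_dm(rng, n)
            res = mrm(d1, [d2, d3], permutations=n_perm, seed=s)
            p = res.p_values.iloc[1]
        elif test == "anova":
            _, p = oneway_anova(rng.normal(size=n), labels)
        elif test == "mannwhitney":
            _, p = mann_whitney_u(rng.normal(size=n // 2), rng.normal(size=n - n // 2))
        elif test == "regression":
            res = linear_regression(rng.normal(size=n), rng.normal(size=n))
            p = res.p
        else:
            raise ValueError(f"unknown test {test!r}")
        rejections += p < alpha
    return rejections / n_sims


# ---------------------------------------------------------------------------
# Planted-structure recovery
# ---------------------------------------------------------------------------

def _recovery_config(n_otus: int, rho: float, seed: int) -> tuple[CommunityConfig, list[str]]:
    cfg = CommunityConfig(n_otus=n_otus, seed=seed)
    ids = cfg.otu_ids()
    # plant the block on mid-ladder (typical-abundance) OTUs
    mid = [ids[k] for k in np.linspace(n_otus * 0.4, n_otus * 0.7, 5).astype(int)]
    cfg.correlation_blocks = [CorrelationBlock(otus=tuple(mid), rho=rho)]
    return cfg, mid


def _design_frame(n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "disturbance": ["P"] * n, "surface": ["G"] * n,
        "block": ["P1"] * n, "site": ["s1"] * n,
    }, index=[f"s{i:03d}" for i in range(n)])


def edge_recovery(n_seeds: int = 20, n_samples: int = 50, n_otus: int = 50,
                  rho: float = 0.9, r_threshold: float = 0.7,
                  p_threshold: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """(precision, recall) of planted-pair recovery, averaged over seeds."""
    rng = np.random.default_rng(seed)
    design = _design_frame(n_samples)
    precisions, recalls = [], []
    for _ in range(n_seeds):
        cfg, _ = _recovery_config(n_otus, rho, seed=int(rng.integers(2**31)))
        table = generate_counts(design, cfg, "bacteria")
        truth = set(planted_truth(cfg).correlated_pairs)
        res = conet.spearman_all_pairs(table)
        net = conet.build_network(res, r_threshold, p_threshold, domains="bacteria")
        found = {tuple(sorted(e)) for e in net.edges}
        tp = len(found & truth)
        precisions.append(tp / len(found) if found else 1.0)
        recalls.append(tp / len(truth))
    return float(np.mean(precisions)), float(np.mean(recalls))


def null_edge_rate(n_seeds: int = 10, n_samples: int = 30, n_otus: int = 50,
                   seed: int = 0) -> float:
    """False-positive edge rate with no planted correlation at all."""
    rng = np.random.default_rng(seed)
    design = _design_frame(n_samples)
    rates = []
    for _ in range(n_seeds):
        cfg = CommunityConfig(n_otus=n_otus, seed=int(rng.integers(2**31)))
        table = generate_counts(design, cfg, "bacteria")
        res = conet.spearman_all_pairs(table)
        net = conet.build_network(res, domains="bacteria")
        rates.append(net.number_of_edges() / len(res))
    return float(np.mean(rates))


def enrichment_recovery(n_seeds: int = 20, n_per_group: int = 20, n_otus: int = 50,
                        log2fc: float = 2.0, planted_fraction: float = 0.2,
                        seed: int = 0) -> float:
    """Mean recovered enrichment ratio with a planted enriched OTU set."""
    from .permstats import enrichment_ratio

    rng = np.random.default_rng(seed)
    design = pd.concat([
        _design_frame(n_per_group),
        pd.DataFrame({
            "disturbance": ["C"] * n_per_group, "surface": ["G"] * n_per_group,
            "block": ["C1"] * n_per_group, "site": ["s1"] * n_per_group,
        }, index=[f"c{i:03d}" for i in range(n_per_group)]),
    ])
    ratios = []
    n_planted = int(round(planted_fraction * n_otus))
    for _ in range(n_seeds):
        cfg = CommunityConfig(n_otus=n_otus, seed=int(rng.integers(2**31)))
        ids = cfg.otu_ids()
        spread = [ids[k] for k in np.linspace(0, n_otus - 1, n_planted).astype(int)]
        cfg.enriched_sets = [EnrichmentSet(group={"disturbance": "P"},
                                           otus=tuple(spread), log2fc=log2fc)]
        table = generate_counts(design, cfg, "bacteria")
        report = enrichment_ratio(table, design, focal={"disturbance": "P"})
        ratios.append(report.ratio)
    return float(np.mean(ratios))


def emf_shift_detection(n_reps: int = 200, n_per_group: int = 25,
                        shift_sd: float = 1.0, seed: int = 0) -> float:
    """Fraction of replicates in which a +shift_sd-on-all-functions group
    has the larger mean EMF."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        a = rng.normal(size=(n_per_group, 7))
        b = rng.normal(size=(n_per_group, 7)) + shift_sd
        m = pd.DataFrame(np.vstack([a, b]),
                         columns=[f"f{k}" for k in range(7)])
        scores = emf_scores(m)
        hits += scores.iloc[n_per_group:].mean() > scores.iloc[:n_per_group].mean()
    return hits / n_reps
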